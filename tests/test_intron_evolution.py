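import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from conftest import brute_force_posteriors
from genarch.io_formats import GeneModel, OrthologTable, SpeciesTree
from genarch.intron_evolution import (TwoStateFit, assign_site_ages,
                                      bootstrap_vmr, brute_force_loglik,
                                      classify_sites,
                                      cluster_presence_profiles,
                                      fit_gain_loss_model, gain_loss_ratio,
                                      intron_density, map_intron_sites,
                                      phylostratigraphy_table,
                                      phylostratigraphy_test, pruning_loglik,
                                      reconstruct_ancestral_sites,
                                      regulatory_overlap,
                                      select_marker_orthoclusters,
                                      sites_to_matrix, variance_to_mean)
from genarch.synthetic_data import simulate_intron_history


def make_table(cells):
    """cells: {og: {sp: n_copies}} over species sp0..sp9."""
    species = [f"sp{i}" for i in range(10)]
    groups = {og: {sp: [f"{og}_{sp}_{k}" for k in range(per.get(sp, 0))]
                   for sp in species}
              for og, per in cells.items()}
    return OrthologTable(groups=groups, species=species)


class TestMarkerSelection:
    def test_universal_single_copy_kept(self):
        table = make_table({"OG1": {f"sp{i}": 1 for i in range(10)}})
        assert "OG1" in select_marker_orthoclusters(table)

    def test_below_fraction_dropped(self):
        table = make_table({"OG1": {f"sp{i}": 1 for i in range(7)}})
        assert select_marker_orthoclusters(table) == {}

    def test_one_paralog_species_tolerated_best_copy_kept(self):
        cells = {f"sp{i}": 1 for i in range(8)}
        cells["sp8"] = 2
        table = make_table({"OG1": cells})
        scores = {"OG1_sp8_0": 1.0, "OG1_sp8_1": 5.0}
        kept = select_marker_orthoclusters(table, paralog_scores=scores)
        assert kept["OG1"]["sp8"] == "OG1_sp8_1"

    def test_two_paralog_species_rejected(self):
        cells = {f"sp{i}": 1 for i in range(8)}
        cells["sp8"] = cells["sp9"] = 2
        table = make_table({"OG1": cells})
        assert select_marker_orthoclusters(table) == {}

    def test_missing_scores_fall_back_to_longest(self, caplog):
        cells = {f"sp{i}": 1 for i in range(8)}
        cells["sp8"] = 2
        table = make_table({"OG1": cells})
        lengths = {"OG1_sp8_0": 100, "OG1_sp8_1": 300}
        with caplog.at_level("WARNING", logger="genarch"):
            kept = select_marker_orthoclusters(table, protein_lengths=lengths)
        assert kept["OG1"]["sp8"] == "OG1_sp8_1"
        assert "longest" in caplog.text


def gene_with_introns(species, intron_offsets, n_codons=40):
    """Single-scaffold gene whose introns sit after the given coding-nt counts."""
    segs = []
    pos = 1
    prev = 0
    for off in intron_offsets:
        segs.append((pos, pos + (off - prev) - 1))
        pos = segs[-1][1] + 101
        prev = off
    segs.append((pos, pos + (n_codons * 3 - prev) - 1))
    return GeneModel(f"{species}_g", species, "scf", "+", segs)


class TestSiteMapping:
    def test_phase0_maps_to_downstream_codon(self):
        genes = {"spA": gene_with_introns("spA", [30])}
        aln = {"spA": "M" * 40}
        sites = map_intron_sites("OG1", aln, genes)
        assert (sites[0].column, sites[0].phase) == (11, 0)

    def test_phase1_maps_to_interrupted_codon(self):
        genes = {"spA": gene_with_introns("spA", [31])}
        aln = {"spA": "M" * 40}
        sites = map_intron_sites("OG1", aln, genes)
        assert (sites[0].column, sites[0].phase) == (11, 1)

    def test_same_column_different_phase_distinct_sites(self):
        genes = {"spA": gene_with_introns("spA", [31]),
                 "spB": gene_with_introns("spB", [32])}
        aln = {"spA": "M" * 40, "spB": "M" * 40}
        sites = map_intron_sites("OG1", aln, genes)
        assert len(sites) == 2
        assert {(s.column, s.phase) for s in sites} == {(11, 1), (11, 2)}

    def test_gaps_shift_alignment_columns(self):
        genes = {"spA": gene_with_introns("spA", [30])}
        aln = {"spA": "--" + "M" * 40}
        sites = map_intron_sites("OG1", aln, genes)
        assert sites[0].column == 13

    def test_shared_site_merges_across_species(self):
        genes = {"spA": gene_with_introns("spA", [30]),
                 "spB": gene_with_introns("spB", [30]),
                 "spC": gene_with_introns("spC", [])}
        aln = {sp: "M" * 40 for sp in genes}
        sites = map_intron_sites("OG1", aln, genes,
                                 all_species=["spA", "spB", "spC", "spD"])
        assert len(sites) == 1
        assert sites[0].presence == {"spA": "present", "spB": "present",
                                     "spC": "absent", "spD": "missing"}

    def test_length_mismatch_raises(self):
        genes = {"spA": gene_with_introns("spA", [30])}
        with pytest.raises(ValueError, match="ungapped"):
            map_intron_sites("OG1", {"spA": "M" * 39}, genes)


class TestSiteClassification:
    def make_sites(self, column=5):
        from genarch.intron_evolution import IntronSite
        return [IntronSite("OG1", column, 0, {"spA": "present"})]

    def test_gap_free_full_coverage_conserved(self):
        aln = {f"sp{i}": "M" * 10 for i in range(10)}
        sites = classify_sites(self.make_sites(), aln, n_species_total=10)
        assert sites[0].classification == "conserved"

    def test_thirty_percent_gaps_ambiguous(self):
        aln = {f"sp{i}": ("MMMM-MMMMM" if i < 3 else "M" * 10)
               for i in range(10)}
        sites = classify_sites(self.make_sites(), aln, n_species_total=10)
        assert sites[0].classification == "ambiguous"

    def test_eighty_percent_coverage_boundary_inclusive(self):
        aln = {f"sp{i}": "M" * 10 for i in range(8)}
        sites = classify_sites(self.make_sites(), aln, n_species_total=10)
        assert sites[0].classification == "conserved"

    def test_mostly_gapped_window_unclassifiable(self):
        aln = {f"sp{i}": ("MMMM-MMMMM" if i < 6 else "M" * 10)
               for i in range(10)}
        sites = classify_sites(self.make_sites(), aln, n_species_total=10)
        assert sites[0].classification == "unclassifiable"


def fixed_fit(tree, gain, loss, root_prior=0.5):
    return TwoStateFit(tree=tree, gain={nm: gain for nm in tree.node_names},
                       loss={nm: loss for nm in tree.node_names},
                       root_prior=root_prior, log_likelihood=0.0,
                       converged=True, n_iter=0)


class TestLikelihood:
    def test_pruning_equals_brute_force(self, balanced8):
        rng = np.random.default_rng(0)
        fit = TwoStateFit(
            tree=balanced8,
            gain={nm: float(rng.uniform(0.05, 1.5))
                  for nm in balanced8.node_names},
            loss={nm: float(rng.uniform(0.05, 1.5))
                  for nm in balanced8.node_names},
            root_prior=0.37, log_likelihood=0.0, converged=True, n_iter=0)
        m = pd.DataFrame(rng.integers(0, 2, size=(25, 8)).astype(float),
                         columns=list("ABCDEFGH"))
        m.iloc[3, 2] = np.nan
        assert pruning_loglik(m, balanced8, fit) == pytest.approx(
            brute_force_loglik(m, balanced8, fit), abs=1e-8)
        m2 = m.dropna()
        assert pruning_loglik(m2, balanced8, fit, True) == pytest.approx(
            brute_force_loglik(m2, balanced8, fit, True), abs=1e-8)

    def test_single_branch_closed_form(self):
        # parent absent, child present over one branch of length t
        tree = SpeciesTree.from_newick("(A:1.5)R;")
        g, l = 0.4, 0.6
        fit = fixed_fit(tree, g, l, root_prior=0.0)
        m = pd.DataFrame([[1.0]], columns=["A"])
        expect = (g / (g + l)) * (1 - np.exp(-(g + l) * 1.5))
        assert pruning_loglik(m, tree, fit) == pytest.approx(np.log(expect))

    def test_all_absent_matrix_rejected(self, quartet):
        m = pd.DataFrame(np.zeros((5, 4)), columns=list("ABCD"))
        with pytest.raises(ValueError, match="all-absent"):
            fit_gain_loss_model(m, quartet)


class TestReconstruction:
    def test_posteriors_match_enumeration(self, quartet):
        rng = np.random.default_rng(1)
        fit = TwoStateFit(
            tree=quartet,
            gain={nm: float(rng.uniform(0.05, 1.0)) for nm in quartet.node_names},
            loss={nm: float(rng.uniform(0.05, 1.0)) for nm in quartet.node_names},
            root_prior=0.4, log_likelihood=0.0, converged=True, n_iter=0)
        m = pd.DataFrame(rng.integers(0, 2, size=(16, 4)).astype(float),
                         columns=list("ABCD"))
        m.iloc[2, 1] = np.nan
        recon = reconstruct_ancestral_sites(m, quartet, fit)
        post, gain, loss = brute_force_posteriors(m, quartet, fit)
        idx = quartet.index()
        got = recon.posterior[idx.names].to_numpy()
        # leaf entries are pinned to observations where present
        assert np.allclose(got, post, atol=1e-6)
        assert np.allclose(recon.gain_posterior[idx.names].to_numpy(), gain,
                           atol=1e-6)
        assert np.allclose(recon.loss_posterior[idx.names].to_numpy(), loss,
                           atol=1e-6)

    def test_ubiquitous_site_present_at_root(self, balanced8):
        m = pd.DataFrame(np.ones((10, 8)), columns=list("ABCDEFGH"))
        fit = fixed_fit(balanced8, gain=0.02, loss=1e-4)
        recon = reconstruct_ancestral_sites(m, balanced8, fit)
        assert (recon.posterior["R"] > 0.99).all()

    def test_leaf_specific_gain_localises_to_terminal_branch(self, quartet):
        m = pd.DataFrame([[1.0, 0.0, 0.0, 0.0]], columns=list("ABCD"))
        fit = fixed_fit(quartet, gain=0.2, loss=0.2, root_prior=0.5)
        recon = reconstruct_ancestral_sites(m, quartet, fit)
        gains = recon.gain_posterior.iloc[0]
        assert gains.idxmax() == "A"

    def test_forced_loss_when_gain_rate_zero(self, quartet):
        # root present, no gains possible: absence at leaf B demands a loss
        m = pd.DataFrame([[1.0, 0.0, 1.0, 1.0]], columns=list("ABCD"))
        fit = fixed_fit(quartet, gain=1e-9, loss=0.3, root_prior=1.0 - 1e-12)
        recon = reconstruct_ancestral_sites(m, quartet, fit)
        _, _, loss = brute_force_posteriors(m, quartet, fit)
        idx = quartet.index()
        assert np.allclose(recon.loss_posterior[idx.names].to_numpy(), loss,
                           atol=1e-6)
        assert recon.loss_posterior.iloc[0]["B"] > 0.99

    def test_posteriors_within_unit_interval_and_pinned_at_leaves(self, quartet):
        sim = simulate_intron_history(quartet, 100, 0.3, 0.3, 0.5, seed=5)
        m = sim.extant_matrix.astype(float)
        m = m[m.sum(axis=1) > 0]
        fit = fit_gain_loss_model(m, quartet)
        recon = reconstruct_ancestral_sites(m, quartet, fit)
        vals = recon.posterior.to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()
        for sp in "ABCD":
            assert np.array_equal(recon.posterior[sp], m[sp])


class TestRateRecovery:
    def test_rates_recovered_on_star_phylogeny(self, star8):
        g = l = 0.1
        sim = simulate_intron_history(star8, 5000, g, l, 0.5, seed=1)
        m = sim.extant_matrix.astype(float)
        m = m[m.sum(axis=1) > 0]
        fit = fit_gain_loss_model(m, star8)
        for nm, ghat in fit.gain.items():
            if sim.true_gains[nm] >= 20:
                assert abs(ghat - g) / g < 0.25
        for nm, lhat in fit.loss.items():
            if sim.true_losses[nm] >= 20:
                assert abs(lhat - l) / l < 0.25

    def test_balanced_gains_and_losses_with_stationary_root(self, balanced8):
        # g = l and stationary root: tree-wide expected gains ~ losses
        sim = simulate_intron_history(balanced8, 10000, 0.2, 0.2, 0.5, seed=2)
        m = sim.extant_matrix.astype(float)
        m = m[m.sum(axis=1) > 0]
        fit = fixed_fit(balanced8, 0.2, 0.2, root_prior=0.5)
        recon = reconstruct_ancestral_sites(m, balanced8, fit)
        total_g = recon.expected_gains.sum()
        total_l = recon.expected_losses.sum()
        assert abs(total_g - total_l) / total_g < 0.05


class TestSummaries:
    @pytest.mark.parametrize("p_g,p_l,expected",
                             [(5.0, 5.0, 0.0), (10.0, 1.0, 1.0),
                              (1.0, 10.0, -1.0)])
    def test_gain_loss_ratio(self, p_g, p_l, expected):
        assert gain_loss_ratio(p_g, p_l) == pytest.approx(expected, abs=1e-5)

    def test_intron_density(self):
        assert intron_density(100, 20.0) == 5.0
        assert intron_density(0.0, 20.0) == 0.0
        with pytest.raises(ValueError):
            intron_density(10, 0.0)

    def test_vmr_constant_counts_zero(self):
        assert variance_to_mean(np.array([5.0, 5.0, 5.0])) == 0.0

    def test_vmr_poisson_near_one(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(50, size=500)
        # VMR sampling SE for Poisson ~ sqrt(2/(n-1))
        se = np.sqrt(2 / 499)
        assert abs(variance_to_mean(counts) - 1.0) < 3 * se

    def test_vmr_zero_mean_nan(self, caplog):
        with caplog.at_level("WARNING", logger="genarch"):
            assert np.isnan(variance_to_mean(np.zeros(10)))

    def test_bootstrap_vmr_deterministic(self, quartet):
        sim = simulate_intron_history(quartet, 60, 0.3, 0.3, 0.5, seed=3)
        m = sim.extant_matrix.astype(float)
        m = m[m.sum(axis=1) > 0]
        fit = fit_gain_loss_model(m, quartet)
        a = bootstrap_vmr(m, quartet, fit, n_reps=20, seed=11)
        b = bootstrap_vmr(m, quartet, fit, n_reps=20, seed=11)
        pd.testing.assert_series_equal(a, b)
        assert (a.dropna() >= 0).all()


class TestProfileClustering:
    def test_identical_rows_merge_first(self):
        profiles = pd.DataFrame([[1, 0, 1, 0, 1], [1, 0, 1, 0, 1],
                                 [0, 1, 0, 1, 0]],
                                index=["n1", "n2", "n3"], dtype=float)
        Z, leaves, _ = cluster_presence_profiles(profiles)
        assert Z[0, 2] == 0.0

    def test_anticorrelated_rows_distance_two(self):
        from genarch.intron_evolution import spearman_distance_matrix
        profiles = pd.DataFrame([[1, 2, 3, 4], [4, 3, 2, 1]],
                                index=["a", "b"], dtype=float)
        D = spearman_distance_matrix(profiles)
        assert D.loc["a", "b"] == pytest.approx(2.0)

    def test_constant_row_gets_unit_distance(self, caplog):
        from genarch.intron_evolution import spearman_distance_matrix
        profiles = pd.DataFrame([[1, 1, 1, 1], [1, 2, 3, 4]],
                                index=["a", "b"], dtype=float)
        with caplog.at_level("WARNING", logger="genarch"):
            D = spearman_distance_matrix(profiles)
        assert D.loc["a", "b"] == 1.0

    def test_clade_specific_gains_recovered(self):
        # two clades with clade-specific site blocks: recovered in >= 95/100
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            block_a = rng.random((2, 40)) < 0.8
            block_b = rng.random((3, 40)) < 0.8
            profiles = np.zeros((5, 80))
            profiles[:2, :40] = block_a
            profiles[2:, 40:] = block_b
            df = pd.DataFrame(profiles,
                              index=["a1", "a2", "b1", "b2", "b3"],
                              dtype=float)
            Z, leaves, _ = cluster_presence_profiles(df)
            import scipy.cluster.hierarchy as sch
            order = sorted(df.index)
            labels = dict(zip(order, sch.fcluster(Z, 2, criterion="maxclust")))
            if (labels["a1"] == labels["a2"] != labels["b1"]
                    and labels["b1"] == labels["b2"] == labels["b3"]):
                hits += 1
        assert hits >= 95


def fisher_enumeration(table):
    """Exact two-sided Fisher p by enumerating tables with fixed margins."""
    table = np.asarray(table)
    r1, r2 = table.sum(axis=1)
    c1, _ = table.sum(axis=0)
    n = table.sum()
    probs = []
    obs = None
    for a in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = (scipy.special.comb(r1, a) * scipy.special.comb(r2, c1 - a)
             / scipy.special.comb(n, c1))
        probs.append(p)
        if a == table[0, 0]:
            obs = p
    probs = np.array(probs)
    return float(probs[probs <= obs * (1 + 1e-9)].sum())


import scipy.special


class TestPhylostratigraphy:
    def test_printed_counts_give_p_one(self):
        _, p = phylostratigraphy_test([[74, 3], [465, 22]])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_balanced_table_p_one(self):
        _, p = phylostratigraphy_test([[1, 1], [1, 1]])
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [[[10, 0], [0, 10]], [[5, 2], [3, 9]],
                                       [[74, 3], [465, 22]]])
    def test_matches_hypergeometric_enumeration(self, table):
        _, p = phylostratigraphy_test(table)
        assert p == pytest.approx(fisher_enumeration(table), rel=1e-9)

    def test_invariant_under_simultaneous_row_col_swap(self):
        table = np.array([[74, 3], [465, 22]])
        _, p1 = phylostratigraphy_test(table)
        _, p2 = phylostratigraphy_test(table[::-1, ::-1])
        assert p1 == pytest.approx(p2)

    def test_overlap_rule_uses_interval_length_fraction(self):
        introns = pd.DataFrame({"chrom": ["c", "c"], "start": [0, 100],
                                "end": [50, 150]}, index=["i1", "i2"])
        # interval of length 20: 10 bp inside i1 (50%), 9 bp inside i2 (45%)
        intervals = pd.DataFrame({"chrom": ["c", "c"], "start": [40, 141],
                                  "end": [60, 161]})
        flags = regulatory_overlap(introns, intervals, overlap_fraction=0.5)
        assert flags["i1"] and not flags["i2"]

    def test_empty_age_class_rejected(self):
        ages = pd.Series(["recent", "recent"], index=["i1", "i2"])
        flags = pd.Series([True, False], index=["i1", "i2"])
        with pytest.raises(ValueError, match="empty age class"):
            phylostratigraphy_table(ages, flags)

    def test_age_assignment_from_reconstruction(self, quartet):
        m = pd.DataFrame([[1.0, 0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0]],
                         columns=list("ABCD"))
        fit = fixed_fit(quartet, 0.2, 0.2)
        recon = reconstruct_ancestral_sites(m, quartet, fit)
        ages = assign_site_ages(recon, "A")
        assert ages.iloc[0] == "recent"
        assert ages.iloc[1] == "ancestral"
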