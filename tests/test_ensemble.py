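import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from survsig import (
    Dichotomy,
    ExpressionMatrix,
    Signature,
    SurvivalData,
    classify_stability,
    cluster_dichotomies,
    cluster_samples_and_silhouette,
    dichotomy_distance,
    differential_expression,
    integrate_signatures,
    orient_dichotomy,
    rank_genes,
)
from survsig.ensemble import linkage_to_newick


def make_surv(time, event):
    ids = [f"s{i:03d}" for i in range(len(time))]
    return SurvivalData(ids, np.asarray(time, float), np.asarray(event, int))


def oriented(assign, good_group):
    return Dichotomy(
        assignment=np.asarray(assign),
        orientation={good_group: "good", 3 - good_group: "poor"},
    )


class TestOrientDichotomy:
    def test_late_events_group_is_good(self):
        surv = make_surv([1, 2, 3, 20, 21, 22], [1, 1, 1, 1, 1, 1])
        d = orient_dichotomy(Dichotomy(np.array([1, 1, 1, 2, 2, 2])), surv)
        assert d.orientation[2] == "good"
        assert d.orientation[1] == "poor"

    def test_tie_broken_toward_larger_group(self):
        # identical survival on both sides, group 1 larger
        surv = make_surv([5, 5, 5, 5, 5, 5], [1, 1, 1, 1, 1, 1])
        d = orient_dichotomy(Dichotomy(np.array([1, 1, 1, 1, 2, 2])), surv)
        assert d.orientation[1] == "good"

    def test_invariant_to_code_swap(self):
        surv = make_surv([1, 2, 3, 20, 21, 22], [1, 1, 0, 1, 0, 1])
        a = orient_dichotomy(Dichotomy(np.array([1, 1, 1, 2, 2, 2])), surv)
        b = orient_dichotomy(Dichotomy(np.array([2, 2, 2, 1, 1, 1])), surv)
        assert np.array_equal(a.prognosis_labels(), b.prognosis_labels())


class TestDichotomyDistance:
    def test_identical_zero(self):
        a = oriented([1, 1, 2, 2], 1)
        assert dichotomy_distance(a, a) == 0.0

    def test_flipped_orientation_one(self):
        a = oriented([1, 1, 2, 2], 1)
        b = oriented([1, 1, 2, 2], 2)
        assert dichotomy_distance(a, b) == 1.0

    def test_half_disagreement(self):
        a = oriented([1, 1, 2, 2], 1)
        b = oriented([1, 2, 1, 2], 1)
        assert dichotomy_distance(a, b) == 0.5

    def test_unoriented_errors(self):
        a = oriented([1, 1, 2, 2], 1)
        b = Dichotomy(np.array([1, 1, 2, 2]))
        with pytest.raises(ValueError):
            dichotomy_distance(a, b)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        ds = []
        for _ in range(3):
            assign = rng.integers(1, 3, n)
            if assign.min() == assign.max():
                assign[0] = 3 - assign[0]
            ds.append(oriented(assign, int(rng.integers(1, 3))))
        d01 = dichotomy_distance(ds[0], ds[1])
        d12 = dichotomy_distance(ds[1], ds[2])
        d02 = dichotomy_distance(ds[0], ds[2])
        assert d02 <= d01 + d12 + 1e-12


class TestClusterDichotomies:
    def test_identical_pair_merges_first_at_zero(self):
        a = oriented([1, 1, 2, 2], 1)
        b = oriented([1, 1, 2, 2], 1)
        c = oriented([1, 2, 1, 2], 1)
        dm = np.zeros((3, 3))
        for i, x in enumerate((a, b, c)):
            for j, y in enumerate((a, b, c)):
                dm[i, j] = dichotomy_distance(x, y)
        z = cluster_dichotomies(dm)
        assert z[0, 2] == 0.0
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    def test_equidistant_triple_equal_heights(self):
        dm = np.full((3, 3), 0.4)
        np.fill_diagonal(dm, 0.0)
        z = cluster_dichotomies(dm)
        np.testing.assert_allclose(z[:, 2], [0.4, 0.4])

    def test_five_leaf_average_linkage_matches_manual_trace(self):
        # independent naive average-linkage agglomeration as the oracle
        rng = np.random.default_rng(8)
        dm = rng.uniform(0.1, 1.0, (5, 5))
        dm = (dm + dm.T) / 2
        np.fill_diagonal(dm, 0.0)

        clusters = {i: [i] for i in range(5)}
        heights = []
        d = {(i, j): dm[i, j] for i in range(5) for j in range(5) if i < j}
        next_id = 5
        while len(clusters) > 1:
            (i, j), h = min(d.items(), key=lambda kv: kv[1])
            heights.append(h)
            merged = clusters.pop(i) + clusters.pop(j)
            new_d = {}
            for k, members in clusters.items():
                avg = np.mean([dm[x, y] for x in merged for y in members])
                new_d[(min(k, next_id), max(k, next_id))] = avg
            d = {
                key: val
                for key, val in d.items()
                if i not in key and j not in key
            }
            d.update(new_d)
            clusters[next_id] = merged
            next_id += 1

        z = cluster_dichotomies(dm)
        np.testing.assert_allclose(sorted(z[:, 2]), sorted(heights), atol=1e-12)

    def test_single_dichotomy_errors(self):
        with pytest.raises(ValueError):
            cluster_dichotomies(np.zeros((1, 1)))

    def test_newick_has_all_leaves(self):
        dm = np.array([[0, 0.2, 0.6], [0.2, 0, 0.5], [0.6, 0.5, 0]])
        z = cluster_dichotomies(dm)
        nwk = linkage_to_newick(z, ["d1", "d2", "d3"])
        assert nwk.endswith(";")
        for leaf in ("d1", "d2", "d3"):
            assert leaf in nwk


class TestClassifyStability:
    def make_ensemble(self, n_good_votes, k=16, n=1):
        ds = []
        for i in range(k):
            # sample 0 votes good in n_good_votes of the k dichotomies
            good = i < n_good_votes
            assign = np.array([1, 2])  # second sample pads the dichotomy
            ds.append(oriented(assign, 1 if good else 2))
        return ds

    def test_unanimous_good(self):
        ds = self.make_ensemble(16)
        assert classify_stability(ds)[0] == "stable_good"

    def test_13_of_16_stable_12_uncertain(self):
        assert classify_stability(self.make_ensemble(13))[0] == "stable_good"
        assert classify_stability(self.make_ensemble(12))[0] == "uncertain"

    def test_poor_side_symmetric(self):
        assert classify_stability(self.make_ensemble(3))[0] == "stable_poor"

    def test_single_dichotomy_reduces_to_orientation(self):
        d = oriented([1, 2, 1, 2], 1)
        out = classify_stability([d], threshold=1.0)
        assert "uncertain" not in set(out)
        np.testing.assert_array_equal(
            out == "stable_good", d.prognosis_labels() == "good"
        )

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        k, n = int(rng.integers(1, 12)), int(rng.integers(2, 15))
        ds = []
        for _ in range(k):
            assign = rng.integers(1, 3, n)
            if assign.min() == assign.max():
                assign[0] = 3 - assign[0]
            ds.append(oriented(assign, int(rng.integers(1, 3))))
        lo = classify_stability(ds, threshold=0.7)
        hi = classify_stability(ds, threshold=0.9)
        # raising the threshold never moves a sample out of 'uncertain'
        assert np.all((lo != "uncertain") | (hi == "uncertain"))


class TestRankGenes:
    def _sig(self, seed, members, importance=None):
        n = 4
        assign = np.array([1, 1, 2, 2])
        imp = importance or {m: 0.5 for m in members}
        return Signature(
            seed=seed,
            members=members,
            statistic=1.0,
            log10_p=-1.0,
            dichotomy=Dichotomy(assign),
            importance=imp,
        )

    def test_gene_in_every_signature(self):
        sigs = [self._sig(f"s{i}", [f"s{i}", "common"]) for i in range(4)]
        r = rank_genes(sigs)
        assert r.probe_ids[0] == "common"
        assert r.n_signatures[0] == 4
        assert r.mean_importance[0] == pytest.approx(0.5)

    def test_absent_gene_not_ranked(self):
        r = rank_genes([self._sig("a", ["a", "b"])])
        assert "c" not in r.probe_ids

    def test_occurrence_totals_conserved(self):
        sigs = [
            self._sig("a", ["a", "b", "c"]),
            self._sig("b", ["b", "c"]),
            self._sig("d", ["d"]),
        ]
        r = rank_genes(sigs)
        assert sum(r.n_signatures) == sum(len(s.members) for s in sigs)

    def test_reference_membership_counts(self):
        # sixteen published signature memberships used as plain input data:
        # the most recurrent gene appears in 9 of the 16
        memberships = [
            ["PCSK5", "AKAP12", "NPR3", "AGPAT5", "GMFB", "C6orf141", "1569202_x_at", "KCNH8"],
            ["FST", "AKAP12", "ULBP2", "SLC25A43", "EI24", "1563467_at", "CLDN8"],
            ["POSTN", "AKAP12", "AGPAT5", "ATL3", "SLC44A2"],
            ["AKAP12", "241867_at", "ADAMTS5", "APLP2", "PITPNC1", "1556983_a_at"],
            ["KIAA1462", "DCBLD2", "ADIPOQ", "FAM217B", "C17orf48"],
            ["DCBLD2", "AKAP12", "GUSBP11", "CDR2L", "MGC16703", "METTL4"],
            ["NPR3", "DZIP1", "243820_at", "238109_at", "236795_at", "DNAJC4", "FOXA1", "EMID2"],
            ["AKAP12", "ISM1", "C11orf9", "244026_at", "ARHGAP9", "NOL3", "AP2A1"],
            ["PAPPA", "NT5E", "DUSP7", "230711_at", "CD96", "ABI2"],
            ["ETV1", "LONRF3", "NGEF", "RAB2A", "U2AF2", "CPO"],
            ["KIAA1462", "AKAP12", "UGGT2", "231989_s_at"],
            ["SRGAP2P1", "AKAP12", "SNX16", "NT5E"],
            ["LOC100132891", "DCBLD2", "ADIPOQ", "SLFN5"],
            ["DCBLD2", "ADCY7", "EHD2"],
            ["CTGF", "FERMT1", "AKAP12", "CDK1"],
            ["EFHA2", "ST18", "ACACB"],
        ]
        sigs = [self._sig(m[0], m) for m in memberships]
        r = rank_genes(sigs)
        assert r.probe_ids[0] == "AKAP12"
        assert r.n_signatures[0] == 9


class TestDifferentialExpression:
    def _expr_and_stability(self, shift_probes=0, n_per_group=30, n_probes=50, seed=0, shift=1.0):
        rng = np.random.default_rng(seed)
        n = 2 * n_per_group + 4
        values = rng.normal(0, 0.5, (n_probes, n))
        stability = np.array(
            ["stable_good"] * n_per_group
            + ["stable_poor"] * n_per_group
            + ["uncertain"] * 4,
            dtype=object,
        )
        values[:shift_probes, n_per_group : 2 * n_per_group] += shift
        expr = ExpressionMatrix(
            [f"p{i:03d}" for i in range(n_probes)],
            [f"s{i:03d}" for i in range(n)],
            values,
        )
        return expr, stability

    def test_planted_shift_detected(self):
        expr, stab = self._expr_and_stability(shift_probes=20, seed=1)
        table = differential_expression(expr, stab)
        top = set(table.loc[table["selected"], "probe_id"])
        planted = {f"p{i:03d}" for i in range(20)}
        assert len(top & planted) >= 18
        assert len(top - planted) <= 2

    def test_null_rarely_selects(self):
        hits = 0
        for seed in range(10):
            expr, stab = self._expr_and_stability(shift_probes=0, seed=seed)
            table = differential_expression(expr, stab)
            hits += int(table["selected"].sum())
        assert hits <= 2

    def test_fold_change_gate(self):
        # strong p-value but sub-threshold fold change is not selected
        expr, stab = self._expr_and_stability(shift_probes=5, seed=3, shift=0.3)
        table = differential_expression(expr, stab)
        sub = table.iloc[:5]
        assert (2.0 ** sub["log_fc"].abs() < 1.5).all()
        assert not sub["selected"].any()

    def test_small_group_errors(self):
        expr, _ = self._expr_and_stability()
        stab = np.array(
            ["stable_good"] + ["stable_poor"] * 5 + ["uncertain"] * 58, dtype=object
        )
        with pytest.raises(ValueError):
            differential_expression(expr, stab)


class TestClusterSamplesAndSilhouette:
    def test_ideal_separation(self):
        rng = np.random.default_rng(2)
        profile_a = rng.normal(0, 1, 20)
        profile_b = -profile_a
        cols = [profile_a + rng.normal(0, 0.01, 20) for _ in range(10)] + [
            profile_b + rng.normal(0, 0.01, 20) for _ in range(10)
        ]
        expr = ExpressionMatrix(
            [f"p{i}" for i in range(20)],
            [f"s{i:02d}" for i in range(20)],
            np.array(cols).T,
        )
        labels, sil = cluster_samples_and_silhouette(expr)
        assert sil > 0.95
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[-1]

    def test_homogeneous_blob_low_silhouette(self):
        rng = np.random.default_rng(5)
        expr = ExpressionMatrix(
            [f"p{i}" for i in range(30)],
            [f"s{i:02d}" for i in range(24)],
            rng.normal(0, 1, (30, 24)),
        )
        _, sil = cluster_samples_and_silhouette(expr)
        assert sil < 0.3

    def test_matches_manual_silhouette(self):
        # oracle: correlation distance + silhouette computed with plain loops
        rng = np.random.default_rng(9)
        values = rng.normal(0, 1, (8, 12))
        values[:, 6:] += np.linspace(1, 3, 8)[:, None]
        expr = ExpressionMatrix(
            [f"p{i}" for i in range(8)], [f"s{i:02d}" for i in range(12)], values
        )
        labels, sil = cluster_samples_and_silhouette(expr)

        dist = 1.0 - np.corrcoef(values.T)
        np.fill_diagonal(dist, 0.0)
        svals = []
        for i in range(12):
            same = [j for j in range(12) if labels[j] == labels[i] and j != i]
            other = [j for j in range(12) if labels[j] != labels[i]]
            a = np.mean(dist[i, same])
            b = np.mean(dist[i, other])
            svals.append((b - a) / max(a, b))
        assert sil == pytest.approx(np.mean(svals), abs=1e-9)

    def test_too_few_probes_errors(self):
        expr = ExpressionMatrix(["p1"], ["a", "b", "c", "d"], np.arange(4.0)[None, :])
        with pytest.raises(ValueError):
            cluster_samples_and_silhouette(expr)


class TestIntegrateSignatures:
    def test_integration_invariants(self):
        rng = np.random.default_rng(10)
        n = 30
        surv = make_surv(rng.exponential(10, n), rng.integers(0, 2, n) | 0)
        surv.event[:5] = 1
        sigs = []
        for i in range(4):
            assign = rng.integers(1, 3, n)
            if assign.min() == assign.max():
                assign[0] = 3 - assign[0]
            sigs.append(
                Signature(
                    seed=f"g{i}",
                    members=[f"g{i}"],
                    statistic=1.0,
                    log10_p=-1.0,
                    dichotomy=Dichotomy(assign),
                    importance={f"g{i}": 1.0},
                )
            )
        res = integrate_signatures(sigs, surv)
        assert res.distance_matrix.shape == (4, 4)
        np.testing.assert_allclose(res.distance_matrix, res.distance_matrix.T)
        np.testing.assert_allclose(np.diag(res.distance_matrix), 0.0)
        assert len(res.stability) == n
        assert res.linkage is not None
        assert all(d.is_oriented for d in res.dichotomies)
        total = sum(res.ranking.n_signatures)
        assert total == sum(len(s.members) for s in sigs)
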