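import numpy as np
import pandas as pd
import pytest
from scipy import stats

from serostab.biopsy import (
    BiopsyExpression,
    bh_adjust,
    build_validation_table,
    heatmap_order,
    map_probes_to_genes,
    moderated_two_group_test,
    serum_outcome_spearman,
    severity_correlation,
)
from serostab.synthetic import BiopsyTruth, generate_biopsy

# ---------------------------------------------------------------------------
# independent oracles


def bh_oracle(p):
    """Brute-force step-up BH adjustment."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(1.0, p[i] * m / rank_from_top)
        running_min = min(running_min, val)
        adj[i] = running_min
    return adj


def midrank(v):
    v = np.asarray(v, float)
    ranks = np.empty(len(v))
    order = np.argsort(v, kind="stable")
    sv = v[order]
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Rank-then-Pearson with midranks."""
    rx, ry = midrank(x), midrank(y)
    return np.corrcoef(rx, ry)[0, 1]


def naive_average_linkage(points):
    """Independent agglomerative clustering: average pairwise Euclidean.

    Returns the merge sequence as frozensets of leaf indices.
    """
    clusters = {i: [i] for i in range(len(points))}
    merges = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean(
                    [
                        np.linalg.norm(points[i] - points[j])
                        for i in clusters[a]
                        for j in clusters[b]
                    ]
                )
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        _, a, b = best
        merges.append(frozenset(clusters[a] + clusters[b]))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


def linkage_merge_sets(link):
    """Convert a scipy-style linkage list into merged-leaf frozensets."""
    n = len(link) + 1
    members = {i: [i] for i in range(n)}
    out = []
    for idx, (a, b, _, _) in enumerate(link):
        merged = members[int(a)] + members[int(b)]
        members[n + idx] = merged
        out.append(frozenset(merged))
    return out


# ---------------------------------------------------------------------------


class TestProbeMapping:
    def _expr(self, probes, values):
        return pd.DataFrame(
            values, index=probes, columns=[f"s{i}" for i in range(len(values[0]))]
        )

    def test_extension_probes_excluded(self, rng):
        probes = ["1007_at", "1007_x_at", "1008_s_at", "1009_at"]
        expr = self._expr(probes, rng.normal(0, 1, (4, 6)))
        ann = pd.DataFrame(
            {"uniprot": ["P1", "P1", "P2", "P3"], "gene": ["A", "A", "B", "C"]},
            index=probes,
        )
        gene_expr, unmapped = map_probes_to_genes(expr, ann, ["P1", "P2", "P3"])
        assert set(gene_expr["probe_id"]) == {"1007_at", "1009_at"}
        assert unmapped == ["P2"]

    def test_max_variance_probe_kept(self):
        probes = ["2001_at", "2002_at"]
        vals = np.array([[0.0, 1.0, 0.0, 1.0], [0.0, 4.0, 0.0, 4.0]])
        expr = self._expr(probes, vals)
        ann = pd.DataFrame(
            {"uniprot": ["P1", "P1"], "gene": ["A", "A"]}, index=probes
        )
        gene_expr, _ = map_probes_to_genes(expr, ann)
        assert list(gene_expr["probe_id"]) == ["2002_at"]

    def test_unannotated_probe_rejected(self, rng):
        expr = self._expr(["1_at", "2_at"], rng.normal(0, 1, (2, 4)))
        ann = pd.DataFrame({"uniprot": ["P1"], "gene": ["A"]}, index=["1_at"])
        with pytest.raises(ValueError, match="without annotation"):
            map_probes_to_genes(expr, ann)


class TestModeratedTest:
    def _dataset(self, rng, n_genes=300, effect=0.0, sd=0.3, n1=6, n2=17):
        cols = [f"n{i}" for i in range(n1)] + [f"d{i}" for i in range(n2)]
        groups = pd.Series(["normal"] * n1 + ["DMD"] * n2, index=cols)
        base = rng.normal(7, 1, n_genes)[:, None]
        vals = base + rng.normal(0, sd, (n_genes, n1 + n2))
        vals[:, :n1] += effect
        expr = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                            columns=cols)
        return expr, groups

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(42)
        expr, groups = self._dataset(rng, n_genes=500)
        res = moderated_two_group_test(expr, groups)
        _, p = stats.kstest(res["p"], "uniform")
        assert p > 0.01

    def test_planted_effect_fold_change(self):
        """A +1 log2 normal-vs-DMD effect reads out as ~2-fold linear change."""
        fcs = []
        for rep in range(200):
            rng = np.random.default_rng(rep)
            expr, groups = self._dataset(rng, n_genes=30, effect=1.0)
            res = moderated_two_group_test(expr, groups)
            fcs.append(res["fold_change"].mean())
        assert 1.8 <= float(np.mean(fcs)) <= 2.2

    def test_sign_convention_dmd_higher_is_negative(self):
        rng = np.random.default_rng(3)
        expr, groups = self._dataset(rng, n_genes=50, effect=-2.0)
        res = moderated_two_group_test(expr, groups)
        assert (res["fold_change"] < 0).mean() > 0.95

    def test_moderation_shrinks_extreme_variances(self):
        rng = np.random.default_rng(5)
        expr, groups = self._dataset(rng, n_genes=400)
        res = moderated_two_group_test(expr, groups)
        welch = [
            stats.ttest_ind(
                expr.loc[g, groups[groups == "normal"].index],
                expr.loc[g, groups[groups == "DMD"].index],
            ).pvalue
            for g in expr.index[:50]
        ]
        # moderated p-values exist and are finite; they differ from plain t
        assert np.isfinite(res["p"]).all()
        assert not np.allclose(res["p"].iloc[:50], welch)

    def test_too_small_group_rejected(self):
        rng = np.random.default_rng(0)
        expr, groups = self._dataset(rng, n_genes=10, n1=1)
        with pytest.raises(ValueError, match=">=2"):
            moderated_two_group_test(expr, groups)


class TestSeverityCorrelation:
    def test_decreasing_with_grade_is_toward_mild_positive(self):
        grades = ["mild", "moderate", "severe"]
        expr = np.array([6.0, 5.0, 4.0])
        rho, _ = severity_correlation(expr, grades)
        assert rho == pytest.approx(1.0)

    def test_increasing_with_grade_is_negative(self):
        grades = [1, 2, 3]
        expr = np.array([1.0, 2.0, 3.0])
        rho, _ = severity_correlation(expr, grades)
        assert rho == pytest.approx(-1.0)

    def test_tied_grades_monotone_signal_keeps_sign(self):
        # with tied grades |rho| < 1 but the toward-mild sign is preserved
        grades = ["mild", "mild", "moderate", "moderate", "severe", "severe"]
        expr = np.array([6.0, 5.9, 5.0, 4.9, 4.0, 3.9])
        rho, _ = severity_correlation(expr, grades)
        assert 0.9 < rho < 1.0

    def test_tied_grades_match_midrank_oracle(self, rng):
        grades = rng.integers(1, 4, 28)
        expr = rng.normal(0, 1, 28)
        rho, _ = severity_correlation(expr, grades)
        assert rho == pytest.approx(-spearman_oracle(expr, grades), abs=1e-12)

    def test_all_equal_grades_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            rho, p = severity_correlation(np.arange(5.0), [1, 1, 1, 1, 1])
        assert np.isnan(rho)


class TestSerumSpearman:
    def test_rank_invariance_under_monotone_transform(self, rng):
        x = rng.normal(0, 1, 20)
        rho, _ = serum_outcome_spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_anti_monotone(self, rng):
        x = rng.normal(0, 1, 20)
        rho, _ = serum_outcome_spearman(x, -(x**3))
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_pearson_oracle(self, rng):
        for _ in range(20):
            x = rng.integers(0, 5, 10).astype(float)  # ties likely
            y = rng.normal(0, 1, 10)
            rho, _ = serum_outcome_spearman(x, y)
            assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])

    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(0.0001, 1, 15)
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_order_invariant(self, rng):
        p = rng.uniform(0.0001, 1, 30)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestHeatmapOrder:
    def test_identical_columns_adjacent(self, rng):
        base = rng.normal(0, 1, (6, 5))
        m = np.column_stack([base, base[:, 2]])
        df = pd.DataFrame(m, columns=[f"s{i}" for i in range(6)])
        order = heatmap_order(df)["col_order"]
        i, j = order.index("s2"), order.index("s5")
        assert abs(i - j) == 1

    def test_block_matrix_separates_sample_groups(self, rng):
        left = rng.normal(0, 0.1, (8, 5)) + 3
        right = rng.normal(0, 0.1, (8, 5)) - 3
        m = pd.DataFrame(
            np.column_stack([left, right]),
            columns=[f"L{i}" for i in range(5)] + [f"R{i}" for i in range(5)],
        )
        m.iloc[:, :] += rng.normal(0, 0.01, m.shape)
        order = heatmap_order(m)["col_order"]
        labels = ["L" if c.startswith("L") else "R" for c in order]
        # one contiguous block per group
        assert labels == sorted(labels) or labels == sorted(labels, reverse=True)

    def test_merge_sequence_matches_naive_oracle(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (6, 6)))
        res = heatmap_order(m)
        z = (m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True))
        z = z / m.to_numpy().std(axis=1, keepdims=True)
        expected = naive_average_linkage(list(z))
        got = linkage_merge_sets(res["row_linkage"])
        assert got == expected

    def test_constant_rows_dropped(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (4, 5)))
        m.iloc[2] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            res = heatmap_order(m)
        assert 2 not in res["row_order"]


class TestValidationPipeline:
    def test_planted_signs_recovered_and_orientation_consistent(self):
        """Genes up in DMD and up with severity get (-FC, - toward-mild)."""
        de = {f"G{i}": (-2.0 if i % 2 else 2.0) for i in range(20)}
        sev = {f"G{i}": (0.6 if i % 2 else -0.6) for i in range(20)}
        truth = BiopsyTruth(de_genes=de, severity_genes=sev)
        bexpr, ann = generate_biopsy(truth, seed=12, n_background=100)
        res = moderated_two_group_test(
            bexpr.expression, bexpr.diagnosis()
        )
        diag = bexpr.diagnosis()
        dyst = [s for s in bexpr.samples if diag[s] != "normal"]
        grades = bexpr.grades()[dyst]
        n_correct = 0
        for g, eff in de.items():
            probe = ann.index[ann["gene"] == g][0]
            fc = res.loc[probe, "fold_change"]
            rho, _ = severity_correlation(
                bexpr.expression.loc[probe, dyst], grades
            )
            if np.sign(fc) == np.sign(eff) and np.sign(rho) == np.sign(-sev[g]):
                n_correct += 1
        assert n_correct >= 0.95 * len(de)

    def test_build_validation_table_structure(self, rng):
        genes = [f"G{i}" for i in range(6)]
        truth = BiopsyTruth(
            de_genes={g: 1.5 for g in genes},
            severity_genes={g: -0.5 for g in genes},
        )
        uni = {g: f"U{i:04d}" for i, g in enumerate(genes)}
        bexpr, _ = generate_biopsy(
            truth, seed=9, n_background=80, gene_to_uniprot=uni
        )
        n_subj = 20
        subjects = [f"S{i}" for i in range(n_subj)]
        serum = pd.DataFrame(
            rng.normal(0, 1, (n_subj, 6)), index=subjects,
            columns=[f"APT{i}" for i in range(6)],
        )
        outcomes = pd.DataFrame(
            {"TTSTAND_velocity": rng.normal(0.25, 0.05, n_subj),
             "6MWT": rng.normal(380, 50, n_subj)},
            index=subjects,
        )
        panels = {
            "TTSTAND_velocity": pd.DataFrame(
                {"protein": serum.columns[:4], "uniprot": [uni[g] for g in genes[:4]],
                 "gene": genes[:4]}
            ),
            "6MWT": pd.DataFrame(
                {"protein": serum.columns[2:], "uniprot": [uni[g] for g in genes[2:]],
                 "gene": genes[2:]}
            ),
        }
        tables = build_validation_table(panels, serum, outcomes, bexpr)
        t = tables["TTSTAND_velocity"]
        assert len(t) == 4
        for col in ("serum_rho", "serum_p_adj", "fold_change",
                    "fold_change_p_adj", "severity_rho", "severity_p_adj"):
            assert col in t.columns
        # joint family: shared gene G2 must carry identical adjusted DE p
        a = tables["TTSTAND_velocity"].set_index("gene")
        b = tables["6MWT"].set_index("gene")
        assert a.loc["G2", "fold_change_p_adj"] == pytest.approx(
            b.loc["G2", "fold_change_p_adj"]
        )
        assert (t["fold_change_p_adj"] >= t["fold_change_p"] - 1e-15).all()

    def test_metadata_invariants_enforced(self, rng):
        expr = pd.DataFrame(rng.normal(0, 1, (3, 2)), index=["a_at", "b_at", "c_at"],
                            columns=["s1", "s2"])
        meta = pd.DataFrame(
            {"diagnosis": ["DMD", "DMD"], "grade": ["mild", "unknown"]},
            index=["s1", "s2"],
        )
        with pytest.raises(ValueError, match="without grade"):
            BiopsyExpression(expression=expr, metadata=meta)
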