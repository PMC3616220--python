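"""Pearson correlation and correlation-threshold signature derivation."""

import numpy as np
import pandas as pd
import pytest

from wntsig.signature import (
    AnchorSet,
    TargetPanel,
    derive_signature,
    pearson_r,
)
from wntsig.synthetic import gen_anchor_correlated_matrix
from .conftest import make_matrix


class TestPearson:
    def test_self_correlation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson_r(x, x).r == pytest.approx(1.0)
        assert pearson_r(x, -x).r == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 10.0])
        expected = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert pearson_r(x, y).r == pytest.approx(expected, abs=1e-12)

    def test_ci_brackets_r_and_p_from_t(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = pearson_r(x, y)
        assert res.ci95[0] < res.r < res.ci95[1]
        from scipy import stats
        t = res.r * np.sqrt(28 / (1 - res.r**2))
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), 28), rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _toy_setup(values, panel_genes, anchor_genes=("A",)):
    probes = [f"{g}_at" for g in list(anchor_genes) + panel_genes]
    m = make_matrix(values, probes=probes)
    ann = pd.Series({f"{g}_at": g for g in list(anchor_genes) + panel_genes})
    anchors = AnchorSet.resolve("A", list(anchor_genes), ann, m)
    panel = TargetPanel({g: [f"{g}_at"] for g in panel_genes})
    return m, anchors, panel


class TestDeriveSignature:
    def test_perfect_correlate_included_positive(self):
        base = [1.0, 2.0, 3.0, 4.0, 5.0]
        m, anchors, panel = _toy_setup([base, base], ["G1"])
        res = derive_signature(m, anchors, panel)
        assert res.n_probes == res.n_genes == 1
        e = res.entries[0]
        assert e.sign == "positive" and e.mean_r == pytest.approx(1.0)

    def test_membership_matches_brute_force_mean_r(self, rng):
        # 5 panel probes engineered so mean_r straddles the 0.4 threshold
        n = 40
        anchor = rng.normal(size=n)
        rows = [anchor]
        rhos = [0.9, 0.45, 0.35, -0.6, -0.2]
        for rho in rhos:
            eps = rng.normal(size=n)
            rows.append(rho * (anchor - anchor.mean()) / anchor.std()
                        + np.sqrt(1 - rho**2) * eps)
        genes = [f"G{i}" for i in range(5)]
        m, anchors, panel = _toy_setup(np.array(rows), genes)
        res = derive_signature(m, anchors, panel)
        # independent oracle: per-pair Pearson via np.corrcoef
        expected = {}
        for i, g in enumerate(genes):
            r = np.corrcoef(rows[0], rows[i + 1])[0, 1]
            if r >= 0.4:
                expected[g] = "positive"
            elif r <= -0.4:
                expected[g] = "negative"
        got = {e.gene_symbol: e.sign for e in res.entries}
        assert got == expected
        for e in res.entries:
            r = np.corrcoef(rows[0], rows[genes.index(e.gene_symbol) + 1])[0, 1]
            assert e.mean_r == pytest.approx(r, abs=1e-12)

    def test_pooled_mean_over_two_anchors(self, rng):
        n = 30
        a1 = rng.normal(size=n)
        a2 = rng.normal(size=n)
        g = rng.normal(size=n)
        m, anchors, panel = _toy_setup(
            np.array([a1, a2, g]), ["G1"], anchor_genes=("A1", "A2")
        )
        anchors.name = "A1/A2"
        res = derive_signature(m, anchors, panel, threshold=0.01)
        mean_r = 0.5 * (np.corrcoef(g, a1)[0, 1] + np.corrcoef(g, a2)[0, 1])
        if res.entries:
            assert res.entries[0].mean_r == pytest.approx(mean_r, abs=1e-12)
        else:
            assert abs(mean_r) < 0.01

    def test_noise_genes_rarely_pass_at_n200(self):
        # 1000 independent null panel genes at n=200: per-gene pass
        # probability at |r| >= 0.4 is far below 1%
        matrix, truth = gen_anchor_correlated_matrix(
            n_samples=200, n_null_genes=1000, planted=[], seed=7,
            anchor_genes=["A"],
        )
        ann = truth.annotation
        anchors = AnchorSet.resolve("A", ["A"], ann, matrix)
        panel = TargetPanel(truth.panel_probes)
        res = derive_signature(matrix, anchors, panel)
        assert res.n_probes / 1000 < 0.01

    def test_threshold_monotone_shrinkage(self, rng):
        matrix, truth = gen_anchor_correlated_matrix(
            n_samples=30, n_null_genes=50,
            planted=[(f"G{i}", 0.5) for i in range(10)], seed=11,
            anchor_genes=["A"],
        )
        anchors = AnchorSet.resolve("A", ["A"], truth.annotation, matrix)
        panel = TargetPanel(truth.panel_probes)
        prev = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            cur = {e.probe_id for e in
                   derive_signature(matrix, anchors, panel, threshold=thr).entries}
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_sample_order_permutation_invariance(self, rng):
        matrix, truth = gen_anchor_correlated_matrix(
            n_samples=25, n_null_genes=20, planted=[("G0", 0.7)], seed=3,
            anchor_genes=["A"],
        )
        anchors = AnchorSet.resolve("A", ["A"], truth.annotation, matrix)
        panel = TargetPanel(truth.panel_probes)
        res1 = derive_signature(matrix, anchors, panel)
        perm = list(rng.permutation(matrix.sample_ids))
        from wntsig.expression import ExpressionMatrix
        shuffled = ExpressionMatrix(matrix.data[perm], is_log2=True)
        res2 = derive_signature(shuffled, anchors, panel)
        assert [(e.gene_symbol, e.probe_id, e.sign) for e in res1.entries] == \
               [(e.gene_symbol, e.probe_id, e.sign) for e in res2.entries]
        for e1, e2 in zip(res1.entries, res2.entries):
            assert e1.mean_r == pytest.approx(e2.mean_r, abs=1e-12)

    def test_counts_report_genes_and_probes_separately(self, rng):
        # one gene with 3 passing probes, one with 2, so 2 genes / 5 probes
        n = 50
        anchor = rng.normal(size=n)
        a_std = (anchor - anchor.mean()) / anchor.std()
        rows = [anchor]
        probes, ann = ["A_at"], {"A_at": "A"}
        panel = {"G1": [], "G2": []}
        for gene, k in (("G1", 3), ("G2", 2)):
            for j in range(k):
                eps = rng.normal(size=n)
                rows.append(0.9 * a_std + np.sqrt(1 - 0.81) * eps)
                pid = f"{gene}_{j}_at"
                probes.append(pid)
                ann[pid] = gene
                panel[gene].append(pid)
        m = make_matrix(np.array(rows), probes=probes)
        anchors = AnchorSet.resolve("A", ["A"], pd.Series(ann), m)
        res = derive_signature(m, anchors, TargetPanel(panel))
        assert res.n_genes == 2
        assert res.n_probes == 5

    def test_bad_threshold_and_empty_panel(self, small_matrix):
        ann = pd.Series({"pA": "A"})
        anchors = AnchorSet.resolve("A", ["A"], ann, small_matrix)
        panel = TargetPanel({"ZZ": ["zz_at"]})
        with pytest.raises(ValueError, match="threshold"):
            derive_signature(small_matrix, anchors, panel, threshold=1.5)
        with pytest.raises(ValueError, match="no panel probe"):
            derive_signature(small_matrix, anchors, panel)
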