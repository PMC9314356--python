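import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from polyres.ld import (LDPanel, clump, exclude_risk_variants, ld_r2,
                        risk_orthogonality_certificate)


def _panel(dosages, positions=None, chrom=None, window_bp=1_000_000):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    variants = pd.DataFrame({
        "snp_id": [f"v{i}" for i in range(m)],
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": positions if positions is not None else np.arange(1, m + 1) * 1000,
    })
    return LDPanel(variants=variants, dosages=dosages, window_bp=window_bp)


def _cand(ids, ps, positions=None, chrom="1", betas=None):
    n = len(ids)
    return pd.DataFrame({
        "snp_id": ids, "chrom": chrom,
        "pos": positions if positions is not None else np.arange(1, n + 1) * 1000,
        "effect_allele": "A", "other_allele": "G",
        "beta": betas if betas is not None else np.full(n, 0.1),
        "se": 0.1, "p": ps,
    })


class TestR2:
    def test_identical_columns_give_one(self, rng):
        col = rng.binomial(2, 0.4, 20).astype(float)
        panel = _panel(np.column_stack([col, col]))
        assert ld_r2(panel, "v0", "v1") == pytest.approx(1.0)

    def test_complement_column_gives_one(self, rng):
        col = rng.binomial(2, 0.4, 20).astype(float)
        panel = _panel(np.column_stack([col, 2.0 - col]))
        assert ld_r2(panel, "v0", "v1") == pytest.approx(1.0)

    def test_six_sample_hand_fixture(self):
        a = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        b = np.array([1, 1, 2, 0, 0, 1], dtype=float)
        panel = _panel(np.column_stack([a, b]))
        # manual Pearson r from raw sums
        n = 6
        r_manual = (n * (a * b).sum() - a.sum() * b.sum()) / np.sqrt(
            (n * (a * a).sum() - a.sum() ** 2) * (n * (b * b).sum() - b.sum() ** 2))
        assert ld_r2(panel, "v0", "v1") == pytest.approx(r_manual**2, abs=1e-9)

    def test_self_r2_is_one(self, rng):
        col = rng.binomial(2, 0.3, 15).astype(float)
        panel = _panel(col[:, None])
        assert ld_r2(panel, "v0", "v0") == pytest.approx(1.0)

    def test_zero_variance_is_nan(self, rng):
        panel = _panel(np.column_stack([np.ones(10),
                                        rng.binomial(2, 0.5, 10)]))
        assert np.isnan(ld_r2(panel, "v0", "v1"))


class TestExcludeRiskVariants:
    def _setup(self, rng):
        # v0: risk SNP; v1 correlated with v0; v2 independent
        g0 = rng.binomial(2, 0.5, 400).astype(float)
        g1 = np.where(rng.uniform(size=400) < 0.9, g0,
                      rng.binomial(2, 0.5, 400)).astype(float)
        g2 = rng.binomial(2, 0.5, 400).astype(float)
        panel = _panel(np.column_stack([g0, g1, g2]),
                       positions=[1000, 11_000, 21_000])
        return panel

    def test_rule_a_removes_low_risk_p(self, rng):
        panel = self._setup(rng)
        cand = _cand(["v0", "v1", "v2"], [0.5, 0.9, 0.9],
                     positions=[1000, 11_000, 21_000])
        risk = _cand(["v0"], [0.4], positions=[1000])
        out = exclude_risk_variants(cand, risk, panel)
        assert "v0" not in set(out["snp_id"])  # risk P = 0.4 < 0.5

    def test_rule_b_removes_ld_partner(self, rng):
        panel = self._setup(rng)
        assert ld_r2(panel, "v0", "v1") >= 0.2
        cand = _cand(["v1", "v2"], [0.9, 0.9], positions=[11_000, 21_000])
        risk = _cand(["v0"], [0.01], positions=[1000])
        out = exclude_risk_variants(cand, risk, panel)
        assert "v1" not in set(out["snp_id"])
        assert "v2" in set(out["snp_id"])

    def test_low_ld_high_p_retained(self, rng):
        panel = self._setup(rng)
        cand = _cand(["v2"], [0.9], positions=[21_000])
        risk = _cand(["v0"], [0.01], positions=[1000])
        out = exclude_risk_variants(cand, risk, panel)
        assert list(out["snp_id"]) == ["v2"]

    def test_outside_window_retained(self, rng):
        g0 = rng.binomial(2, 0.5, 200).astype(float)
        panel = _panel(np.column_stack([g0, g0]),
                       positions=[1000, 2_000_000], window_bp=1_000_000)
        cand = _cand(["v1"], [0.9], positions=[2_000_000])
        risk = _cand(["v0"], [0.01], positions=[1000])
        out = exclude_risk_variants(cand, risk, panel)
        assert list(out["snp_id"]) == ["v1"]  # perfect LD but beyond 1 Mb

    def test_empty_survivors_fatal(self, rng):
        panel = self._setup(rng)
        cand = _cand(["v0"], [0.9], positions=[1000])
        risk = _cand(["v0"], [0.01], positions=[1000])
        with pytest.raises(ValueError, match="no candidate survives"):
            exclude_risk_variants(cand, risk, panel)

    def test_unknown_risk_p_retained_by_rule_a(self, rng):
        panel = self._setup(rng)
        cand = _cand(["v2"], [0.9], positions=[21_000])
        risk = _cand(["v0"], [0.9], positions=[1000])  # nothing risk-associated
        out = exclude_risk_variants(cand, risk, panel)
        assert list(out["snp_id"]) == ["v2"]


def clump_oracle(candidates, dosages, r2_max, window_bp):
    """Exhaustive greedy clumping over the full r2 matrix (independent code)."""
    df = candidates.reset_index(drop=True)
    r = np.corrcoef(dosages, rowvar=False)
    r2 = r * r
    order = sorted(range(len(df)),
                   key=lambda i: (df.loc[i, "p"], df.loc[i, "chrom"],
                                  df.loc[i, "pos"]))
    claimed = set()
    index_rows = []
    for i in order:
        if i in claimed:
            continue
        claimed.add(i)
        index_rows.append(i)
        for j in range(len(df)):
            if j in claimed:
                continue
            same_chrom = df.loc[i, "chrom"] == df.loc[j, "chrom"]
            near = abs(int(df.loc[i, "pos"]) - int(df.loc[j, "pos"])) <= window_bp
            if same_chrom and near and r2[i, j] >= r2_max:
                claimed.add(j)
    return set(df.loc[sorted(index_rows), "snp_id"])


class TestClump:
    def test_independent_variants_identity(self, rng):
        dos = rng.binomial(2, 0.5, size=(500, 6)).astype(float)
        panel = _panel(dos)
        cand = _cand([f"v{i}" for i in range(6)], rng.uniform(0.01, 1, 6))
        out = clump(cand, panel)
        assert set(out["snp_id"]) == set(cand["snp_id"])

    def test_perfect_pair_keeps_smaller_p(self, rng):
        col = rng.binomial(2, 0.5, 50).astype(float)
        panel = _panel(np.column_stack([col, col]))
        cand = _cand(["v0", "v1"], [0.5, 0.01])
        out = clump(cand, panel)
        assert list(out["snp_id"]) == ["v1"]

    @pytest.mark.parametrize("seed", range(10))
    def test_exhaustive_oracle_30_variants(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 200, 30
        base = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        # induce heavy correlation between random column pairs
        for _ in range(12):
            i, j = rng.integers(0, m, 2)
            mask = rng.uniform(size=n) < 0.85
            base[mask, j] = base[mask, i]
        positions = np.sort(rng.integers(1, 3_000_000, m))
        panel = _panel(base, positions=positions.tolist(), window_bp=1_000_000)
        cand = _cand([f"v{i}" for i in range(m)],
                     rng.uniform(size=m).round(3), positions=positions.tolist())
        got = set(clump(cand, panel)["snp_id"])
        expected = clump_oracle(cand, base, 0.2, 1_000_000)
        assert got == expected

    def test_output_pairwise_below_threshold(self, rng):
        n, m = 300, 20
        base = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        for _ in range(8):
            i, j = rng.integers(0, m, 2)
            mask = rng.uniform(size=n) < 0.9
            base[mask, j] = base[mask, i]
        panel = _panel(base)
        cand = _cand([f"v{i}" for i in range(m)], rng.uniform(size=m))
        out = clump(cand, panel)
        kept = list(out["snp_id"])
        for a in kept:
            for b in kept:
                if a != b:
                    assert ld_r2(panel, a, b) < 0.2

    def test_monotone_shrink_in_r2max(self, rng):
        n, m = 300, 15
        base = rng.binomial(2, 0.5, size=(n, m)).astype(float)
        for _ in range(6):
            i, j = rng.integers(0, m, 2)
            mask = rng.uniform(size=n) < 0.7
            base[mask, j] = base[mask, i]
        panel = _panel(base)
        cand = _cand([f"v{i}" for i in range(m)], rng.uniform(size=m))
        sizes = [len(clump(cand, panel, r2_max=r)) for r in (0.05, 0.2, 0.5, 1.01)]
        assert sizes == sorted(sizes)


class TestCertificate:
    def test_passes_on_clean_set(self, rng):
        dos = rng.binomial(2, 0.5, size=(300, 4)).astype(float)
        panel = _panel(dos)
        scored = _cand(["v1", "v3"], [0.9, 0.8], positions=[2000, 4000])
        risk = _cand(["v0"], [0.9], positions=[1000])
        risk_orthogonality_certificate(scored, risk, panel)

    def test_fails_on_risk_associated(self, rng):
        dos = rng.binomial(2, 0.5, size=(300, 2)).astype(float)
        panel = _panel(dos)
        scored = _cand(["v0"], [0.9], positions=[1000])
        risk = _cand(["v0"], [0.01], positions=[1000])
        with pytest.raises(AssertionError, match="risk P"):
            risk_orthogonality_certificate(scored, risk, panel)

    def test_fails_on_ld_partner(self, rng):
        col = rng.binomial(2, 0.5, 300).astype(float)
        panel = _panel(np.column_stack([col, col]), positions=[1000, 2000])
        scored = _cand(["v1"], [0.9], positions=[2000])
        risk = _cand(["v0"], [0.01], positions=[1000])
        with pytest.raises(AssertionError, match="r2"):
            risk_orthogonality_certificate(scored, risk, panel)
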