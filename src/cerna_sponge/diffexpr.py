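"""Normalization, differential-expression testing and DE calling.

The replicate path uses a conditional negative-binomial exact test with
total-count library normalization and a common method-of-moments dispersion:
counts are scaled to a common library size, the per-group sums of a feature
are modelled as NB, and conditioning on their total makes the null split
distribution parameter-free (a negative hypergeometric in the group NB
shapes). The two-sided p-value sums the probabilities of all splits no more
likely than the observed one.

The no-replicate path tests each feature's two counts against the library
size ratio with an exact binomial test; the BH step-up formula is then
applied as an FDR (q-value) estimate.

DE calls follow the strict thresholds |log2FC| > 1 and adjusted p < 0.05
(q < 0.01 on the no-replicate path).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .io_model import ExpressionMatrix


def tpm_normalize(
    counts: ExpressionMatrix, totals: dict[str, float] | None = None
) -> ExpressionMatrix:
    """Per-million scaling: count / total * 1e6.

    ``totals`` optionally supplies per-sample mapped-read totals; by default
    the column sums of the supplied matrix are used, in which case every
    column of the result sums to 1e6.
    """
    if counts.units != "counts":
        raise ValueError("tpm_normalize expects a raw-count matrix")
    df = counts.values.astype(float)
    if totals is None:
        col_totals = df.sum(axis=0)
    else:
        col_totals = pd.Series({s: float(totals[s]) for s in df.columns})
    zero = col_totals[col_totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    tpm = df / col_totals * 1e6
    return ExpressionMatrix(
        values=tpm, biotype=counts.biotype, groups=dict(counts.groups), units="TPM"
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def estimate_common_dispersion(
    norm_counts: np.ndarray, group_idx: list[np.ndarray]
) -> float:
    """Common NB dispersion by method of moments across features.

    Under NB, Var = mu + phi*mu^2, so within-group moments satisfy
    E[s2 - m] = phi*mu^2 and E[m^2 - s2/n] = mu^2; pooling both sides over
    groups and features gives the ratio-of-sums estimator

        phi = sum_f sum_g w_g (s2 - m) / sum_f sum_g w_g (m^2 - s2/n_g)

    which is nearly unbiased even at small group sizes (a per-feature
    median underestimates phi because s2 is right-skewed). Clipped to
    [1e-6, 10].
    """
    num = np.zeros(norm_counts.shape[0])
    den = np.zeros(norm_counts.shape[0])
    for idx in group_idx:
        sub = norm_counts[:, idx]
        n_g = len(idx)
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        w = n_g - 1
        num += w * (s2 - m)
        den += w * (m**2 - s2 / n_g)
    total_den = float(den.sum())
    if total_den <= 0:
        return 1e-6
    return float(np.clip(num.sum() / total_den, 1e-6, 10.0))


def _conditional_nb_pvalue(sa: int, s: int, r_a: float, r_b: float) -> float:
    """Two-sided exact p-value for the split (sa, s-sa) of the total s.

    The conditional null distribution of the group-A sum given the total is
    P(a | s) proportional to C(a+r_a-1, a) * C(s-a+r_b-1, s-a); the p-value
    is the total probability of splits no more likely than the observed one.
    A window of +/-12 conditional SDs around the mode keeps the support
    tractable for large totals (the truncated tail mass is negligible).
    """
    if s == 0:
        return 1.0
    mode = s * r_a / (r_a + r_b)
    spread = np.sqrt(mode * (1.0 + mode / r_a)) + 1.0
    lo = max(0, int(mode - 12 * spread))
    hi = min(s, int(mode + 12 * spread) + 1)
    lo, hi = min(lo, sa), max(hi, sa)
    a = np.arange(lo, hi + 1)
    logw = (
        gammaln(a + r_a)
        - gammaln(a + 1)
        + gammaln(s - a + r_b)
        - gammaln(s - a + 1)
    )
    logw -= logsumexp(logw)
    w_obs = logw[sa - lo]
    return float(np.exp(logsumexp(logw[logw <= w_obs + 1e-10])))


def nb_exact_test(
    counts: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    pseudo_count: float = 0.5,
) -> pd.DataFrame:
    """Per-feature exact NB test between two sample groups (replicate path).

    Returns a DataFrame indexed by feature id with columns mean_A, mean_B
    (normalized means), log2FC (log2((mean_B+c)/(mean_A+c)), pseudo-count
    c=0.5) and p_value. Requires >= 2 samples in each group; callers with
    single samples belong on the no-replicate path.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError(
            "nb_exact_test needs >=2 samples per group; "
            "use binomial_test_noreplicate for single-sample contrasts"
        )
    df = counts.values
    samples = list(group_a) + list(group_b)
    mat = df[samples].to_numpy(float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        bad = [samples[i] for i in np.flatnonzero(lib <= 0)]
        raise ValueError(f"zero-total sample(s): {bad}")
    ref = lib.mean()
    # equalize library sizes (rounded pseudo-counts), as total-count offsets
    norm = np.rint(mat * (ref / lib)).astype(np.int64)
    n_a = len(group_a)
    idx_a = np.arange(n_a)
    idx_b = np.arange(n_a, len(samples))
    phi = estimate_common_dispersion(norm.astype(float), [idx_a, idx_b])
    r_a = n_a / phi
    r_b = len(group_b) / phi

    sa = norm[:, idx_a].sum(axis=1)
    sb = norm[:, idx_b].sum(axis=1)
    mean_a = norm[:, idx_a].mean(axis=1)
    mean_b = norm[:, idx_b].mean(axis=1)
    log2fc = np.log2((mean_b + pseudo_count) / (mean_a + pseudo_count))
    pvals = np.array(
        [
            _conditional_nb_pvalue(int(a), int(a + b), r_a, r_b)
            for a, b in zip(sa, sb)
        ]
    )
    return pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2FC": log2fc,
            "p_value": np.clip(pvals, 0.0, 1.0),
        },
        index=df.index,
    )


def binomial_test_noreplicate(
    counts: ExpressionMatrix,
    sample_a: str,
    sample_b: str,
    pseudo_count: float = 0.5,
) -> pd.DataFrame:
    """Two-proportion exact test for a single-sample-per-group contrast.

    Each feature's count in sample B is tested against Binomial(total,
    L_B/(L_A+L_B)); log2FC uses library-size-normalized counts with a
    pseudo-count.
    """
    df = counts.values
    xa = df[sample_a].to_numpy(float)
    xb = df[sample_b].to_numpy(float)
    la, lb = xa.sum(), xb.sum()
    if la <= 0 or lb <= 0:
        raise ValueError("zero-total sample in no-replicate contrast")
    p0 = lb / (la + lb)
    pvals = np.array(
        [
            binomtest(int(b), int(a + b), p0).pvalue if a + b > 0 else 1.0
            for a, b in zip(xa, xb)
        ]
    )
    ref = (la + lb) / 2.0
    mean_a = xa * ref / la
    mean_b = xb * ref / lb
    log2fc = np.log2((mean_b + pseudo_count) / (mean_a + pseudo_count))
    return pd.DataFrame(
        {"mean_A": mean_a, "mean_B": mean_b, "log2FC": log2fc, "p_value": pvals},
        index=df.index,
    )


def qvalue_noreplicate(p_values) -> np.ndarray:
    """q-values for the no-replicate path (BH step-up as an FDR estimate)."""
    return bh_adjust(p_values)


def call_de(
    results: pd.DataFrame, lfc_cut: float = 1.0, padj_cut: float = 0.05
) -> pd.DataFrame:
    """Attach adjusted p-values and up/down/not_significant calls.

    Strict inequalities: up iff log2FC > lfc_cut and adj_p < padj_cut;
    down iff log2FC < -lfc_cut and adj_p < padj_cut.
    """
    out = results.copy()
    if "adj_p" not in out.columns:
        out["adj_p"] = bh_adjust(out["p_value"].to_numpy())
    sig = out["adj_p"] < padj_cut
    call = np.where(
        sig & (out["log2FC"] > lfc_cut),
        "up",
        np.where(sig & (out["log2FC"] < -lfc_cut), "down", "not_significant"),
    )
    out["call"] = call
    return out


def de_contrast(
    counts: ExpressionMatrix,
    contrast: tuple[str, str],
    lfc_cut: float = 1.0,
    padj_cut: float = 0.05,
    q_cut: float = 0.01,
) -> pd.DataFrame:
    """Full DE table for one (A, B) group contrast, log2FC = log2(B/A).

    Dispatches to the exact NB test (>=2 samples per group) or to the
    binomial no-replicate path (with the stricter q < 0.01 threshold).
    """
    ga, gb = contrast
    samples_a = counts.samples_of(ga)
    samples_b = counts.samples_of(gb)
    if not samples_a or not samples_b:
        raise ValueError(f"contrast {contrast} references an empty group")
    if len(samples_a) >= 2 and len(samples_b) >= 2:
        res = nb_exact_test(counts, samples_a, samples_b)
        return call_de(res, lfc_cut=lfc_cut, padj_cut=padj_cut)
    res = binomial_test_noreplicate(counts, samples_a[0], samples_b[0])
    res["adj_p"] = qvalue_noreplicate(res["p_value"].to_numpy())
    return call_de(res, lfc_cut=lfc_cut, padj_cut=q_cut)


def de_feature_sets(de_table: pd.DataFrame) -> dict[str, set[str]]:
    """{'up': ids, 'down': ids, 'de': union} from a called DE table."""
    up = set(de_table.index[de_table["call"] == "up"])
    down = set(de_table.index[de_table["call"] == "down"])
    return {"up": up, "down": down, "de": up | down}


def overlap_de_sets(set_a, set_b) -> list[str]:
    """Sorted intersection of two DE feature-id sets (Venn overlap)."""
    return sorted(set(set_a) & set(set_b))
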