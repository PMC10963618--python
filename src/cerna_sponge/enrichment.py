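"""Over-representation analysis of gene sets against annotation terms.

The default test is the hypergeometric upper tail: for a term with K
background members, a study set of n genes from an N-gene background, and k
study hits, p = P(X >= k), X ~ Hypergeom(N, K, n); BH correction is applied
across terms and significance declared at adjusted p < 0.05.

An optional length-bias correction replaces each term's p-value by a
Monte-Carlo tail probability under study sets resampled with weights from a
monotone (isotonic) fit of P(DE | gene length) - long genes accrue more
reads and are called DE more easily, which plain ORA ignores.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.isotonic import IsotonicRegression

from .diffexpr import bh_adjust
from .io_model import FeatureAnnotation, TermAnnotation


def hypergeom_ora(
    study: Iterable[str],
    background: Iterable[str],
    terms: Sequence[TermAnnotation],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``study`` within each term.

    Study genes must be drawn from the background (offenders are listed in
    the error); term member sets are intersected with the background.
    Terms with no study hit are reported with p = 1.
    """
    study = set(study)
    background = set(background)
    strays = sorted(study - background)
    if strays:
        raise ValueError(f"study genes absent from background: {strays}")
    n_bg = len(background)
    n_study = len(study)
    rows = []
    for t in terms:
        members = t.member_gene_ids & background
        big_k = len(members)
        k = len(members & study)
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n_study)) if k > 0 else 1.0
        rows.append(
            {
                "term_id": t.term_id,
                "term_name": t.term_name,
                "k": k,
                "n": n_study,
                "K": big_k,
                "N": n_bg,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "n", "K", "N", "p_value"]
    )
    out["adj_p"] = bh_adjust(out["p_value"].to_numpy()) if len(out) else []
    out["significant"] = out["adj_p"] < alpha
    return out.sort_values(["adj_p", "p_value", "term_id"]).reset_index(drop=True)


def length_bias_weights(
    annotations: Sequence[FeatureAnnotation],
    de_flags: Mapping[str, bool],
) -> dict[str, float] | None:
    """Per-gene sampling weights from a monotone fit of P(DE | length).

    Gene lengths are binned into deciles; the per-bin DE fraction is
    smoothed by isotonic regression in length, and each gene's weight is
    the fitted probability at its length (floored away from zero). Returns
    None (correction disabled) with a warning when lengths are missing.
    """
    genes = [a for a in annotations if a.feature_id in de_flags]
    if not genes or any(a.length is None for a in genes):
        warnings.warn(
            "gene lengths unavailable; length-bias correction disabled",
            stacklevel=2,
        )
        return None
    lengths = np.array([a.length for a in genes], dtype=float)
    flags = np.array([bool(de_flags[a.feature_id]) for a in genes], dtype=float)
    deciles = np.quantile(lengths, np.linspace(0, 1, 11))
    bins = np.clip(np.searchsorted(deciles, lengths, side="right") - 1, 0, 9)
    bin_len = np.array(
        [lengths[bins == b].mean() if (bins == b).any() else np.nan for b in range(10)]
    )
    bin_de = np.array(
        [flags[bins == b].mean() if (bins == b).any() else np.nan for b in range(10)]
    )
    ok = ~np.isnan(bin_len)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    iso.fit(bin_len[ok], bin_de[ok])
    fitted = np.maximum(iso.predict(lengths), 1e-6)
    return {a.feature_id: float(w) for a, w in zip(genes, fitted)}


def weighted_resample_ora(
    study: Iterable[str],
    background: Iterable[str],
    terms: Sequence[TermAnnotation],
    weights: Mapping[str, float] | None,
    n_draws: int = 10_000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """ORA with Monte-Carlo null study sets drawn by gene weight.

    Study-set-sized gene sets are resampled without replacement with
    probability proportional to ``weights`` (uniform if None, in which case
    the p-values converge to the hypergeometric ones); per term,
    p = (1 + #{draws with k* >= k_obs}) / (1 + n_draws).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = hypergeom_ora(study, background, terms, alpha=alpha)
    study = set(study)
    bg = sorted(set(background))
    n_study = len(study)
    w = np.array([1.0 if weights is None else weights.get(g, 1e-6) for g in bg])
    logw = np.log(w)
    # Gumbel top-k trick: weighted sampling without replacement, vectorized
    gumbel = rng.gumbel(size=(n_draws, len(bg)))
    keys = logw[None, :] + gumbel
    chosen = np.argpartition(-keys, n_study - 1, axis=1)[:, :n_study]
    member_idx = {
        t.term_id: np.array(
            [i for i, g in enumerate(bg) if g in t.member_gene_ids], dtype=int
        )
        for t in terms
    }
    in_term = np.zeros((len(bg),), dtype=bool)
    mc_p = {}
    for t in terms:
        in_term[:] = False
        in_term[member_idx[t.term_id]] = True
        k_star = in_term[chosen].sum(axis=1)
        k_obs = int(out.loc[out["term_id"] == t.term_id, "k"].iloc[0])
        mc_p[t.term_id] = (1 + int((k_star >= k_obs).sum())) / (1 + n_draws)
    out["p_value"] = out["term_id"].map(mc_p)
    out["adj_p"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["adj_p"] < alpha
    return out.sort_values(["adj_p", "p_value", "term_id"]).reset_index(drop=True)
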