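"""Term over-representation testing for DE gene lists.

For each annotation term the upper hypergeometric tail P(X >= k) is
computed, where k genes of the n-gene DE list fall in a K-gene term drawn
from an N-gene background.  ``method='ease'`` applies the conservative
one-removed variant (the EASE score): k is replaced by max(k - 1, 0) before
taking the tail.  Multiple testing is controlled by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("trimfold")

RESULT_COLUMNS = ["term_id", "term_label", "k", "K", "n", "N",
                  "p_value", "adjusted_p", "fold_enrichment"]


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not 0 <= k <= min(K, n):
        raise ValueError(f"impossible overlap k={k} for K={K}, n={n}")
    return float(hypergeom.sf(k - 1, N, K, n))


def term_enrichment(de_genes: Iterable[str], background: Iterable[str],
                    annotation: pd.DataFrame,
                    method: str = "fisher") -> pd.DataFrame:
    """Over-representation of each term within a DE gene list.

    ``annotation`` is long-format (term_id, term_label, gene_id).  Term
    members outside the background are ignored; a DE gene missing from the
    background is a hard error — it would silently distort every test.
    Results are sorted by p ascending, ties by term id, and carry BH
    adjusted p-values.
    """
    if method not in ("fisher", "ease"):
        raise ValueError(f"unknown method {method!r}")
    background = set(background)
    if not background:
        raise ValueError("background universe is empty")
    de = set(de_genes)
    stray = de - background
    if stray:
        raise ValueError(
            f"DE gene(s) absent from the background universe: "
            f"{', '.join(sorted(stray)[:5])}")
    N, n = len(background), len(de)

    rows = []
    for (tid, label), members in annotation.groupby(
            ["term_id", "term_label"], sort=True)["gene_id"]:
        in_bg = set(members) & background
        K = len(in_bg)
        if K == 0:
            logger.debug("term %s has no members in the background; skipped", tid)
            continue
        k = len(in_bg & de)
        k_eff = max(k - 1, 0) if method == "ease" else k
        p = hypergeom_tail(k_eff, N, K, n)
        fe = (k / n) / (K / N) if n > 0 else np.nan
        rows.append((tid, label, k, K, n, N, p, fe))
    out = pd.DataFrame(rows, columns=["term_id", "term_label", "k", "K",
                                      "n", "N", "p_value", "fold_enrichment"])
    out = out.sort_values(["p_value", "term_id"], kind="mergesort")
    out["adjusted_p"] = adjust_pvalues(out["p_value"].to_numpy())
    return out[RESULT_COLUMNS].reset_index(drop=True)


def adjust_pvalues(p: Sequence[float], method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    if method != "bh":
        raise ValueError(f"unknown adjustment method {method!r}")
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_terms(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    return results[results["adjusted_p"] <= alpha].reset_index(drop=True)
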