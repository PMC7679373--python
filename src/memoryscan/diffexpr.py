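"""Replicate-free differential expression between two count libraries.

The significance engine is the Audic-Claverie test: given a gene observed
``x`` times in a library of ``N1`` mapped reads, the posterior-predictive
probability of seeing ``y`` occurrences in a second library of ``N2`` reads
is

    p(y | x) = r**y * (x + y)! / (x! * y! * (1 + r)**(x + y + 1)),   r = N2 / N1,

i.e. a negative-binomial distribution in ``y`` with ``x + 1`` successes and
success probability ``1 / (1 + r)``.  Two-sided p-values are obtained by
doubling the smaller tail.  All probabilities are evaluated in log space
via log-gamma; tails are summed on whichever side carries less than half
the mass so the accumulated floating error stays bounded.

Calls combine the test with a fold-change cut-off on the RPKM scale and a
Benjamini-Hochberg step-up correction across the genes of one contrast.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .expression import CountMatrix, ExpressionMatrix

__all__ = [
    "ac_log_pmf",
    "ac_pmf",
    "ac_test",
    "ac_test_minlike",
    "benjamini_hochberg",
    "call_differential",
    "deg_sets",
    "write_results",
    "read_results",
]

#: Relative mass below which tail summation is considered converged.
_TAIL_TOL = 1e-12


def _check_count(value, name: str) -> int:
    if isinstance(value, (bool, float)) and not float(value).is_integer():
        raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
    iv = int(value)
    if iv != value or iv < 0:
        raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
    return iv


def ac_log_pmf(y, x: int, ratio: float) -> np.ndarray:
    """log p(y | x) for an array of second-library counts ``y``."""
    x = _check_count(x, "x")
    if ratio <= 0:
        raise ValueError(f"library-size ratio must be positive, got {ratio}")
    y = np.asarray(y)
    if y.size and (np.any(y < 0) or not np.issubdtype(y.dtype, np.integer)):
        if not np.all(np.equal(np.mod(y, 1), 0)) or np.any(y < 0):
            raise ValueError("y must contain non-negative integers")
        y = y.astype(np.int64)
    logr = np.log(ratio)
    log1pr = np.log1p(ratio)
    return (
        y * logr
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * log1pr
    )


def ac_pmf(y: int, x: int, ratio: float) -> float:
    """Probability of observing count ``y`` in library 2 given ``x`` in library 1."""
    y = _check_count(y, "y")
    return float(np.exp(ac_log_pmf(np.array([y]), x, ratio)[0]))


def _lower_tail(x: int, y: int, ratio: float) -> float:
    """P(Y <= y | x) by direct summation of the pmf over 0..y."""
    ks = np.arange(0, y + 1)
    return float(np.exp(logsumexp(ac_log_pmf(ks, x, ratio))))


def _upper_tail(x: int, y: int, ratio: float) -> float:
    """P(Y >= y | x) by chunked summation from y until relative convergence."""
    mean = (x + 1) * ratio
    sd = np.sqrt((x + 1) * ratio * (1.0 + ratio))
    chunk = max(64, int(4 * sd))
    start = y
    log_terms = []
    # Sum outward past the mode until a chunk contributes negligible mass.
    while True:
        ks = np.arange(start, start + chunk)
        lt = ac_log_pmf(ks, x, ratio)
        log_terms.append(lt)
        total = logsumexp(np.concatenate(log_terms))
        if start + chunk > mean and logsumexp(lt) < total + np.log(_TAIL_TOL):
            break
        start += chunk
    return float(np.exp(total))


def ac_test(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic-Claverie p-value for counts ``x`` (library ``n1``) vs ``y`` (``n2``).

    p = min(1, 2 * min(P(Y <= y | x), P(Y >= y | x))), with the complement
    used for whichever tail would otherwise sum more than half the mass.
    """
    x = _check_count(x, "x")
    y = _check_count(y, "y")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    ratio = n2 / n1
    pmf_y = float(np.exp(ac_log_pmf(np.array([y]), x, ratio)[0]))
    mean = (x + 1) * ratio
    if y <= mean:
        lower = _lower_tail(x, y, ratio)
        upper = 1.0 - lower + pmf_y
    else:
        upper = _upper_tail(x, y, ratio)
        lower = 1.0 - upper + pmf_y
    return float(min(1.0, 2.0 * min(lower, upper)))


def ac_test_minlike(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided p-value summing all outcomes no more likely than the observed one.

    Alternative two-sided policy to tail doubling: p = sum over y' of
    p(y' | x) for every y' with p(y' | x) <= p(y | x).
    """
    x = _check_count(x, "x")
    y = _check_count(y, "y")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    ratio = n2 / n1
    mean = (x + 1) * ratio
    sd = np.sqrt((x + 1) * ratio * (1.0 + ratio))
    hi = int(max(y, mean + 20 * sd) + 50)
    lp = ac_log_pmf(np.arange(0, hi + 1), x, ratio)
    # 1+1e-12 relative slack absorbs round-off among analytically equal masses
    keep = lp <= lp[y] + 1e-12
    return float(min(1.0, np.exp(logsumexp(lp[keep]))))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, for order statistics
    p_(1) <= ... <= p_(m).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_differential(
    expr: ExpressionMatrix,
    counts: CountMatrix,
    treated: str,
    control: str,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    pseudocount: float = 0.1,
    two_sided: str = "doubling",
) -> pd.DataFrame:
    """Call up/down/unchanged genes for one treated-vs-control contrast.

    Genes enter the test if present (RPKM >= floor) in at least one of the
    two samples.  Fold change is the treated/control RPKM ratio with a
    small pseudocount on both sides so induction from zero yields a finite,
    large value.  A gene is called up when fold_change >= fold_threshold
    and significant, down when fold_change <= 1/fold_threshold and
    significant; significance is BH-adjusted q < alpha by default, raw
    p < alpha with ``use_adjusted=False``.

    Returns a DataFrame indexed by gene_id with columns
    x, y, N1, N2, fold_change, p_raw, q_bh, call.
    """
    for sample in (treated, control):
        if sample not in counts.counts.columns:
            raise KeyError(f"unknown sample id: {sample!r}")
    if two_sided not in ("doubling", "minlike"):
        raise ValueError(f"two_sided must be 'doubling' or 'minlike', got {two_sided!r}")
    tested = expr.present_in_any([treated, control])
    genes = expr.rpkm.index[tested]
    x = counts.counts.loc[genes, control].to_numpy()
    y = counts.counts.loc[genes, treated].to_numpy()
    n1 = float(counts.library_sizes[control])
    n2 = float(counts.library_sizes[treated])
    fold = (expr.rpkm.loc[genes, treated].to_numpy() + pseudocount) / (
        expr.rpkm.loc[genes, control].to_numpy() + pseudocount
    )
    test = ac_test if two_sided == "doubling" else ac_test_minlike
    p_raw = np.array([test(int(xi), int(yi), n1, n2) for xi, yi in zip(x, y)])
    q_bh = benjamini_hochberg(p_raw)
    sig = (q_bh < alpha) if use_adjusted else (p_raw < alpha)
    call = np.where(
        sig & (fold >= fold_threshold),
        "up",
        np.where(sig & (fold <= 1.0 / fold_threshold), "down", "unchanged"),
    )
    return pd.DataFrame(
        {
            "x": x,
            "y": y,
            "N1": n1,
            "N2": n2,
            "fold_change": fold,
            "p_raw": p_raw,
            "q_bh": q_bh,
            "call": call,
        },
        index=pd.Index(genes, name="gene_id"),
    )


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def deg_sets(results: pd.DataFrame) -> tuple[set, set]:
    """(up, down) gene-id sets from one contrast's results."""
    up = set(results.index[results["call"] == "up"])
    down = set(results.index[results["call"] == "down"])
    return up, down
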