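"""144-feature duplex representation and the nt-1 covariation scan.

Each duplex is described by, for each strand (miRNA, miRNA*), each anchor
(5' end, 3' end) and positions 1..18: the nucleotide identity (72 features)
and the base-pairing status (72 features).  Positions beyond a strand's
length are missing.  Each feature is tested for association with the
identity of the first miRNA nucleotide by Fisher's exact test on the
resulting contingency table; 2x2 tables use the standard hypergeometric
two-sided test, larger tables use exact enumeration of the margin-
constrained table space when small enough and margin-preserving Monte Carlo
otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .duplex_structure import PairingStatus

logger = logging.getLogger(__name__)

N_FEATURES = 144
POSITIONS = 18
STRANDS = ("miRNA", "miRNA*")
ANCHORS = ("5p", "3p")  # from 5' end, from 3' end
BLOCKS = ("identity", "pairing")
MISSING = None

__all__ = [
    "FeatureVector",
    "FeatureKey",
    "CovariationResult",
    "feature_keys",
    "build_feature_vector",
    "fisher_exact",
    "covariation_scan",
    "scan_to_frame",
    "N_FEATURES",
]


@dataclass(frozen=True)
class FeatureKey:
    strand: str  # miRNA | miRNA*
    anchor: str  # 5p | 3p
    position: int  # 1..18
    block: str  # identity | pairing

    def __str__(self) -> str:
        return f"{self.strand}/{self.anchor}/{self.position}/{self.block}"


def feature_keys() -> list[FeatureKey]:
    """The fixed, ordered 144-feature schema."""
    keys = []
    for block in BLOCKS:
        for strand in STRANDS:
            for anchor in ANCHORS:
                for pos in range(1, POSITIONS + 1):
                    keys.append(FeatureKey(strand, anchor, pos, block))
    return keys

FEATURE_KEYS = feature_keys()
assert len(FEATURE_KEYS) == N_FEATURES


@dataclass
class FeatureVector:
    duplex_id: str
    nt1: str
    values: list  # length 144, categorical or None for missing

    def __post_init__(self) -> None:
        if len(self.values) != N_FEATURES:
            raise ValueError(f"feature vector must have {N_FEATURES} values")


def build_feature_vector(
    duplex_id: str,
    seq_a: str,
    seq_b: str,
    status: PairingStatus,
) -> FeatureVector:
    """Feature vector of one duplex (seq_a = miRNA, seq_b = miRNA*)."""
    if not seq_a or not seq_b:
        raise ValueError("both strands must be non-empty")
    seqs = {"miRNA": seq_a, "miRNA*": seq_b}
    paired = {"miRNA": status.paired_a, "miRNA*": status.paired_b}
    values = []
    short_logged = False
    for key in FEATURE_KEYS:
        seq = seqs[key.strand]
        n = len(seq)
        if key.position > n:
            values.append(MISSING)
            short_logged = True
            continue
        idx = key.position - 1 if key.anchor == "5p" else n - key.position
        if key.block == "identity":
            values.append(seq[idx])
        else:
            values.append("paired" if paired[key.strand][idx] else "unpaired")
    if short_logged:
        logger.debug("build_feature_vector: %s has positions past strand length", duplex_id)
    return FeatureVector(duplex_id=duplex_id, nt1=seq_a[0], values=values)


# ---------------------------------------------------------------------------
# Fisher's exact test for r x c tables


def _log_table_prob(table: np.ndarray, logfact_margin: float) -> float:
    """log P(table | margins) under the fixed-margins hypergeometric law."""
    return logfact_margin - gammaln(table + 1.0).sum()


def _enumerate_tables(row_sums, col_sums, cap):
    """All non-negative integer tables with the given margins, or None if
    their number exceeds ``cap``."""
    r, c = len(row_sums), len(col_sums)
    out: list[list[list[int]]] = []

    def fill_row(row_idx, remaining_cols, acc):
        if len(out) > cap:
            raise OverflowError
        if row_idx == r - 1:
            out.append(acc + [list(remaining_cols)])
            return
        target = row_sums[row_idx]

        def fill_cell(col_idx, left, row):
            if col_idx == c - 1:
                if left <= remaining_cols[col_idx]:
                    row = row + [left]
                    rem = [remaining_cols[k] - row[k] for k in range(c)]
                    fill_row(row_idx + 1, rem, acc + [row])
                return
            for v in range(min(left, remaining_cols[col_idx]) + 1):
                fill_cell(col_idx + 1, left - v, row + [v])

        fill_cell(0, target, [])

    try:
        fill_row(0, list(col_sums), [])
    except OverflowError:
        return None
    return [np.array(t) for t in out]


def fisher_exact(
    table,
    method: str = "auto",
    n_mc: int = 10000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    enumeration_cap: int = 10**6,
) -> tuple[float, str]:
    """Two-sided Fisher's exact test on an r x c count table.

    Returns ``(p, method_used)`` with ``method_used`` one of ``exact_2xc``,
    ``exact_network``, ``monte_carlo``.  The two-sided p sums probabilities
    of all margin-preserving tables no more probable than the observed one.
    Degenerate tables (one non-empty row or column) give p = 1.
    """
    table = np.asarray(table, dtype=int)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    # drop empty rows/columns
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        logger.warning("fisher_exact: degenerate table, p = 1")
        return 1.0, "degenerate"

    if table.shape == (2, 2):
        return float(stats.fisher_exact(table, alternative="two-sided")[1]), "exact_2xc"

    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    n = table.sum()
    logfact_margin = (
        gammaln(row_sums + 1.0).sum() + gammaln(col_sums + 1.0).sum() - gammaln(n + 1.0)
    )
    logp_obs = _log_table_prob(table, logfact_margin)
    tol = 1e-9 * abs(logp_obs)

    tables = None
    if method in ("auto", "exact"):
        # cheap upper bound on the table-space size: compositions per free row
        c = table.shape[1]
        log_bound = sum(
            math.lgamma(rs + c) - math.lgamma(rs + 1) - math.lgamma(c)
            for rs in row_sums[:-1]
        )
        if log_bound <= math.log(enumeration_cap):
            tables = _enumerate_tables(list(row_sums), list(col_sums), enumeration_cap)
        if tables is None and method == "exact":
            raise ValueError("exact enumeration exceeds cap; use method='monte_carlo'")
    if tables is not None:
        logps = np.array([_log_table_prob(t, logfact_margin) for t in tables])
        p = float(np.exp(logps[logps <= logp_obs + tol]).sum())
        return min(p, 1.0), "exact_network"

    if rng is None:
        rng = np.random.default_rng(seed)
    sampler = stats.random_table(row_sums, col_sums)
    samples = sampler.rvs(size=n_mc, method="patefield", random_state=rng)
    logps = logfact_margin - gammaln(samples + 1.0).sum(axis=(1, 2))
    hits = int(np.sum(logps <= logp_obs + tol))
    return (1 + hits) / (1 + n_mc), "monte_carlo"


# ---------------------------------------------------------------------------
# the scan


@dataclass
class CovariationResult:
    key: FeatureKey
    table: pd.DataFrame  # nt1 levels x feature levels
    n_used: int
    p: float
    method_used: str


def covariation_scan(
    feature_vectors: Iterable[FeatureVector],
    method: str = "auto",
    n_mc: int = 10000,
    seed: Optional[int] = None,
    enumeration_cap: int = 10**6,
    collapse_nt1_u: bool = False,
) -> list[CovariationResult]:
    """One Fisher test per feature against miRNA nt-1 identity.

    Duplexes missing a value at a feature are dropped pairwise for that
    feature.  ``collapse_nt1_u`` collapses nt1 to U vs non-U (2 x c tables).
    """
    fvs = list(feature_vectors)
    nt1_levels = sorted({fv.nt1 for fv in fvs})
    if len(nt1_levels) < 2:
        raise ValueError("constant miRNA nt 1 across duplexes: nothing to covary")
    rng = np.random.default_rng(seed)

    results = []
    for f_idx, key in enumerate(FEATURE_KEYS):
        pairs = [
            (("U" if fv.nt1 == "U" else "not-U") if collapse_nt1_u else fv.nt1,
             fv.values[f_idx])
            for fv in fvs
            if fv.values[f_idx] is not MISSING
        ]
        if not pairs:
            results.append(
                CovariationResult(key, pd.DataFrame(), 0, 1.0, "degenerate")
            )
            continue
        rows = sorted({a for a, _ in pairs})
        cols = sorted({b for _, b in pairs})
        tab = pd.DataFrame(0, index=rows, columns=cols)
        for a, b in pairs:
            tab.loc[a, b] += 1
        p, used = fisher_exact(
            tab.values, method=method, n_mc=n_mc, rng=rng,
            enumeration_cap=enumeration_cap,
        )
        results.append(CovariationResult(key, tab, len(pairs), p, used))
    return results


def scan_to_frame(results: list[CovariationResult]) -> pd.DataFrame:
    """Tabular scan output ordered for plotting the per-strand/anchor curves."""
    rows = []
    m = len(results)
    for r in results:
        rows.append(
            {
                "strand": r.key.strand,
                "anchor": r.key.anchor,
                "position": r.key.position,
                "block": r.key.block,
                "levels": "x".join(str(s) for s in r.table.shape) if len(r.table) else "0x0",
                "n_used": r.n_used,
                "p": r.p,
                "p_bonferroni": min(1.0, r.p * m),
                "method": r.method_used,
                "neg_log10_p": -math.log10(r.p) if r.p > 0 else math.inf,
            }
        )
    return pd.DataFrame(rows)
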