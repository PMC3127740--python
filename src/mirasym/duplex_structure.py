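"""Intermolecular pair probabilities for a miRNA/miRNA* duplex.

The builtin engine computes an exact inside-outside partition function over
all non-crossing, intermolecular-only pairings of the two strands (Watson-
Crick plus G:U wobble).  Structures are Boltzmann-weighted by a documented
additive score:

* pair scores: G:C +3, A:U +2, G:U +1 (score units, symmetric);
* each maximal run of unpaired nucleotides inside an internal-loop region
  costs ``run_penalty`` (default 0.5);
* internal-loop length imbalance costs ``asym_penalty`` per nt of
  ``|run_a - run_b|`` (default 1.5) -- a Ninio-style asymmetry term, needed
  so terminal wobble registers do not out-compete the canonical duplex
  register;
* exterior (dangling-end) nucleotides are free; temperature-like scale 1.

A position is called paired when its total pairing probability exceeds the
threshold (default 0.5, strict); its partner is the argmax entry.

An ``external`` engine delegates to the ViennaRNA co-folding bindings when
importable, or parses a (i, j, p) probability TSV; otherwise it falls back
to the builtin engine with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_PAIR_SCORES: dict[frozenset, float] = {
    frozenset(("G", "C")): 3.0,
    frozenset(("A", "U")): 2.0,
    frozenset(("G", "U")): 1.0,
}
DEFAULT_RUN_PENALTY = 0.5
DEFAULT_ASYM_PENALTY = 1.5
MAX_LEN = 50

__all__ = [
    "PairProbMatrix",
    "PairingStatus",
    "ScoreModel",
    "extract_duplex",
    "pair_probabilities",
    "pairing_status",
    "read_pair_prob_tsv",
]


@dataclass
class ScoreModel:
    """Additive score for intermolecular duplex structures."""

    gc: float = 3.0
    au: float = 2.0
    gu: float = 1.0
    run_penalty: float = DEFAULT_RUN_PENALTY
    asym_penalty: float = DEFAULT_ASYM_PENALTY

    def pair_score(self, x: str, y: str) -> Optional[float]:
        pair = frozenset((x, y))
        if pair == frozenset(("G", "C")):
            return self.gc
        if pair == frozenset(("A", "U")):
            return self.au
        if pair == frozenset(("G", "U")):
            return self.gu
        return None

    def loop_score(self, run_a: int, run_b: int) -> float:
        """Score contribution of the internal region between consecutive pairs."""
        runs = (run_a > 0) + (run_b > 0)
        return -(self.run_penalty * runs + self.asym_penalty * abs(run_a - run_b))


@dataclass
class PairProbMatrix:
    """p[i-1, j-1] = P(strand-a position i pairs strand-b position j)."""

    seq_a: str
    seq_b: str
    p: np.ndarray

    @property
    def unpaired_a(self) -> np.ndarray:
        return 1.0 - self.p.sum(axis=1)

    @property
    def unpaired_b(self) -> np.ndarray:
        return 1.0 - self.p.sum(axis=0)


@dataclass
class PairingStatus:
    paired_a: np.ndarray
    paired_b: np.ndarray
    partner_a: list  # 1-based b-position or None
    partner_b: list
    threshold: float = 0.5


def _check_seq(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"{name}: non-ACGU symbol(s) {sorted(bad)}")
    if len(seq) > MAX_LEN:
        raise ValueError(f"{name}: length {len(seq)} exceeds {MAX_LEN}")


def extract_duplex(record, profiles) -> tuple[str, str]:
    """Top isoform of each arm of one hairpin -> (miRNA-arm seq, other seq).

    ``profiles`` maps arm -> IsoformProfile (or is a list of profiles).
    Returns sequences ordered (5p, 3p).  Count ties break toward the isoform
    starting closest to the annotated arm start, then 5'-most.
    """
    if not isinstance(profiles, dict):
        profiles = {p.arm: p for p in profiles}
    out = []
    for arm in ("5p", "3p"):
        p = profiles.get(arm)
        if p is None or not p.isoforms:
            raise ValueError(f"hairpin {record.id!r}: arm {arm} has no isoforms")
        out.append(p.top_isoform(record.arm_bounds(arm)[0])[0])
    return out[0], out[1]


def _build_weights(seq_a: str, seq_b: str, model: ScoreModel) -> np.ndarray:
    na, nb = len(seq_a), len(seq_b)
    w = np.zeros((na + 1, nb + 1))
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            s = model.pair_score(seq_a[i - 1], seq_b[j - 1])
            if s is not None:
                w[i, j] = np.exp(s)
    return w


def _loop_weight_table(na: int, nb: int, model: ScoreModel) -> np.ndarray:
    ra = np.arange(na)[:, None]
    rb = np.arange(nb)[None, :]
    runs = (ra > 0).astype(int) + (rb > 0).astype(int)
    return np.exp(-(model.run_penalty * runs + model.asym_penalty * np.abs(ra - rb)))


def pair_probabilities(
    seq_a: str,
    seq_b: str,
    engine: str = "builtin",
    model: Optional[ScoreModel] = None,
    prob_file=None,
) -> PairProbMatrix:
    """Intermolecular pair-probability matrix for two strands.

    ``engine='builtin'`` runs the exact inside-outside partition function
    described in the module docstring.  ``engine='external'`` uses the
    ViennaRNA bindings (or ``prob_file``) when available and otherwise falls
    back to builtin with a warning.
    """
    _check_seq(seq_a, "seq_a")
    _check_seq(seq_b, "seq_b")
    if engine == "external":
        try:
            return _external_engine(seq_a, seq_b, prob_file)
        except ImportError:
            logger.warning("external co-folding engine unavailable; using builtin")
            engine = "builtin"
    if engine != "builtin":
        raise ValueError(f"unknown engine {engine!r}")

    model = model or ScoreModel()
    na, nb = len(seq_a), len(seq_b)
    w = _build_weights(seq_a, seq_b, model)
    L = _loop_weight_table(na + 1, nb + 1, model)

    # Zp[i, j]: sum over structures on pairs {(i', j'): i' <= i, j' >= j}
    # whose last pair (max i, min j) is (i, j).
    Zp = np.zeros((na + 2, nb + 2))
    for i in range(1, na + 1):
        row_w = w[i]
        # loops: run_a = i - ip - 1 for ip in 1..i-1  -> L[i - ip - 1]
        La = L[i - 2 :: -1, :] if i > 1 else None  # row ip-1 -> run i-ip-1
        for j in range(nb, 0, -1):
            if row_w[j] == 0.0:
                continue
            tot = 1.0
            if i > 1 and j < nb:
                # sum over ip in 1..i-1, jp in j+1..nb of Zp[ip, jp] * L[i-ip-1, jp-j-1]
                # La row index ip-1 maps to run_a = i-ip-1 (reversed slice);
                # column index jp-(j+1) equals run_b = jp-j-1 directly
                block = Zp[1:i, j + 1 : nb + 1]
                lw = La[: i - 1, : nb - j]
                tot += float((block * lw).sum())
            Zp[i, j] = row_w[j] * tot

    # Zq[i, j]: structures on pairs {(i', j'): i' >= i, j' <= j} whose first
    # pair (min i, max j) is (i, j).
    Zq = np.zeros((na + 2, nb + 2))
    for i in range(na, 0, -1):
        row_w = w[i]
        Lb = L[: na - i, :]  # row ip-(i+1) -> run ip-i-1
        for j in range(1, nb + 1):
            if row_w[j] == 0.0:
                continue
            tot = 1.0
            if i < na and j > 1:
                block = Zq[i + 1 : na + 1, 1:j]
                # run_b = j - jp - 1 for jp in 1..j-1 -> reverse column order
                lw = Lb[: na - i, : j - 1][:, ::-1]
                tot += float((block * lw).sum())
            Zq[i, j] = row_w[j] * tot

    Z = 1.0 + Zp[1 : na + 1, 1 : nb + 1].sum()
    P = np.zeros((na, nb))
    inner = Zp[1 : na + 1, 1 : nb + 1] * Zq[1 : na + 1, 1 : nb + 1]
    nz = w[1:, 1:] > 0
    P[nz] = inner[nz] / w[1:, 1:][nz] / Z
    return PairProbMatrix(seq_a=seq_a, seq_b=seq_b, p=P)


def _external_engine(seq_a: str, seq_b: str, prob_file=None) -> PairProbMatrix:
    if prob_file is not None:
        return read_pair_prob_tsv(seq_a, seq_b, prob_file)
    import RNA  # noqa: PLC0415

    fc = RNA.fold_compound(f"{seq_a}&{seq_b}")
    fc.pf()
    bpp = fc.bpp()
    na, nb = len(seq_a), len(seq_b)
    P = np.zeros((na, nb))
    for i in range(1, na + 1):
        for j in range(na + 1, na + nb + 1):
            P[i - 1, j - na - 1] = bpp[i][j]
    return PairProbMatrix(seq_a=seq_a, seq_b=seq_b, p=P)


def read_pair_prob_tsv(seq_a: str, seq_b: str, path) -> PairProbMatrix:
    """Adapter: read (i, j, p) rows (1-based strand positions) into the matrix."""
    P = np.zeros((len(seq_a), len(seq_b)))
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            i_s, j_s, p_s = line.split("\t")[:3]
            i, j, p = int(i_s), int(j_s), float(p_s)
            if not (1 <= i <= len(seq_a) and 1 <= j <= len(seq_b)):
                raise ValueError(f"{path}:{lineno}: position out of range")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{path}:{lineno}: probability out of [0,1]")
            P[i - 1, j - 1] = p
    return PairProbMatrix(seq_a=seq_a, seq_b=seq_b, p=P)


def pairing_status(matrix: PairProbMatrix, threshold: float = 0.5) -> PairingStatus:
    """Binary paired/unpaired calls: paired iff total pair probability
    strictly exceeds ``threshold``; partner is the argmax entry."""
    pa = matrix.p.sum(axis=1)
    pb = matrix.p.sum(axis=0)
    paired_a = pa > threshold
    paired_b = pb > threshold
    partner_a = [
        int(np.argmax(matrix.p[i])) + 1 if paired_a[i] else None
        for i in range(len(matrix.seq_a))
    ]
    partner_b = [
        int(np.argmax(matrix.p[:, j])) + 1 if paired_b[j] else None
        for j in range(len(matrix.seq_b))
    ]
    return PairingStatus(
        paired_a=paired_a,
        paired_b=paired_b,
        partner_a=partner_a,
        partner_b=partner_b,
        threshold=threshold,
    )
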