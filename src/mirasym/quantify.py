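"""Map tags onto hairpin arms, designate miRNA vs miRNA*, bin asymmetry.

A tag is admitted to an arm when it matches the hairpin exactly (substring)
and its 5' end lies within ``arm_window`` nt of the annotated arm start.
Multi-mapping tags contribute their full count to every matching hairpin.
The guide strand (miRNA) is the arm with the larger pooled count; ties go to
the 5p arm.  Asymmetry bins partition ratio space: highly asymmetric
(ratio >= 10), moderately asymmetric ([2, 10)), quasisymmetric ([1, 2)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .annotation_io import PreMirnaRecord, ReadLibrary

logger = logging.getLogger(__name__)

HIGHLY = "highly_asymmetric"
MODERATELY = "moderately_asymmetric"
QUASI = "quasisymmetric"
BINS = (HIGHLY, MODERATELY, QUASI)

__all__ = [
    "IsoformProfile",
    "DuplexRecord",
    "profile_isoforms",
    "designate_strands",
    "filter_expressed",
    "bin_asymmetry",
    "build_duplexes",
    "HIGHLY",
    "MODERATELY",
    "QUASI",
    "BINS",
]


@dataclass
class IsoformProfile:
    """Isoforms (sequence, 1-based hairpin start, count) observed on one arm."""

    hairpin_id: str
    arm: str  # 5p | 3p
    isoforms: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(c for _, _, c in self.isoforms)

    def top_isoform(self, arm_start: Optional[int] = None) -> tuple[str, int, int]:
        """Most abundant isoform.

        Count ties are broken toward the isoform starting closest to
        ``arm_start`` (when given), then the 5'-most start.
        """
        if not self.isoforms:
            raise ValueError(f"{self.hairpin_id}/{self.arm}: no isoforms")

        def key(iso):
            seq, start, count = iso
            dist = abs(start - arm_start) if arm_start is not None else 0
            return (-count, dist, start)

        return min(self.isoforms, key=key)


@dataclass
class DuplexRecord:
    """A designated miRNA/miRNA* pair for one hairpin."""

    hairpin_id: str
    mirna_arm: str
    mirna_profile: IsoformProfile
    star_profile: IsoformProfile
    mirna_count: int
    star_count: int
    ratio: float
    bin: str

    @property
    def star_arm(self) -> str:
        return "3p" if self.mirna_arm == "5p" else "5p"

    @property
    def total(self) -> int:
        return self.mirna_count + self.star_count


def profile_isoforms(
    library: ReadLibrary,
    records: Iterable[PreMirnaRecord],
    arm_window: int = 5,
) -> tuple[list[IsoformProfile], int]:
    """Assign tags to hairpin arms; returns (profiles, unmatched read tally).

    Profiles are returned for every annotated arm of every record (possibly
    empty).  Unmatched reads are tallied, never fatal.
    """
    if arm_window < 0:
        raise ValueError("arm_window must be >= 0")
    records = list(records)
    profiles: dict[tuple[str, str], IsoformProfile] = {}
    for rec in records:
        for arm in rec.arms:
            profiles[(rec.id, arm)] = IsoformProfile(rec.id, arm)

    unmatched = 0
    for tag, count in library.counts.items():
        if count == 0:
            continue
        hit = False
        for rec in records:
            start = rec.hairpin_seq.find(tag)
            while start != -1:
                pos1 = start + 1  # 1-based
                for arm in rec.arms:
                    arm_start, arm_end = rec.arm_bounds(arm)
                    if abs(pos1 - arm_start) <= arm_window:
                        profiles[(rec.id, arm)].isoforms.append((tag, pos1, count))
                        hit = True
                start = rec.hairpin_seq.find(tag, start + 1)
        if not hit:
            unmatched += count
    for p in profiles.values():
        p.isoforms.sort(key=lambda iso: (iso[1], iso[0]))
    if unmatched:
        logger.info("profile_isoforms: %d unmatched reads", unmatched)
    return list(profiles.values()), unmatched


def bin_asymmetry(ratio: float) -> str:
    """Bin a miRNA/miRNA* ratio (>= 1, or +inf) into the three asymmetry classes."""
    if not (ratio >= 1.0):
        raise ValueError(f"ratio {ratio} < 1: miRNA must be the more abundant strand")
    if ratio >= 10.0:
        return HIGHLY
    if ratio >= 2.0:
        return MODERATELY
    return QUASI


def designate_strands(
    profiles: list[IsoformProfile],
    annotated_mirna_arm: Optional[str] = None,
) -> Optional[DuplexRecord]:
    """Designate miRNA/miRNA* for one hairpin from its two arm profiles.

    By default the miRNA is the arm with the larger pooled count (tie -> 5p).
    ``annotated_mirna_arm`` overrides abundance-based designation.  Returns
    ``None`` (with a log entry) when either arm is silent.
    """
    if not profiles:
        return None
    hid = profiles[0].hairpin_id
    by_arm = {p.arm: p for p in profiles}
    if set(by_arm) != {"5p", "3p"}:
        logger.info("designate_strands: %s lacks a profiled arm, excluded", hid)
        return None
    c5, c3 = by_arm["5p"].total, by_arm["3p"].total
    if c5 == 0 or c3 == 0:
        if c5 == 0 and c3 == 0:
            logger.info("designate_strands: %s has no reads on either arm", hid)
            return None
        if min(c5, c3) == 0 and max(c5, c3) > 0:
            # one silent arm: the duplex still exists with star_count 0
            pass
    if annotated_mirna_arm is not None:
        mirna_arm = annotated_mirna_arm
    else:
        if c5 == c3:
            logger.info("designate_strands: %s tie (%d reads), miRNA -> 5p", hid, c5)
        mirna_arm = "5p" if c5 >= c3 else "3p"
    star_arm = "3p" if mirna_arm == "5p" else "5p"
    mc, sc = by_arm[mirna_arm].total, by_arm[star_arm].total
    if mc == 0 and sc == 0:
        return None
    ratio = math.inf if sc == 0 else mc / sc
    # annotation-supplied labels may put the minority strand first; the bin
    # rule is literal on the ratio scale, so anything < 2 is quasisymmetric
    bin_ = bin_asymmetry(ratio) if ratio >= 1 else QUASI
    return DuplexRecord(
        hairpin_id=hid,
        mirna_arm=mirna_arm,
        mirna_profile=by_arm[mirna_arm],
        star_profile=by_arm[star_arm],
        mirna_count=mc,
        star_count=sc,
        ratio=ratio,
        bin=bin_,
    )


def filter_expressed(
    duplexes: Iterable[DuplexRecord],
    min_reads: int = 100,
    per_strand: bool = False,
) -> list[DuplexRecord]:
    """Keep duplexes whose pooled hairpin total (or each strand, if
    ``per_strand``) reaches ``min_reads``."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    out = []
    for d in duplexes:
        if per_strand:
            ok = d.mirna_count >= min_reads and d.star_count >= min_reads
        else:
            ok = d.total >= min_reads
        if ok:
            out.append(d)
        else:
            logger.info("filter_expressed: %s dropped (%d reads)", d.hairpin_id, d.total)
    return out


def build_duplexes(
    library: ReadLibrary,
    records: Iterable[PreMirnaRecord],
    arm_window: int = 5,
    min_reads: int = 100,
    per_strand: bool = False,
) -> tuple[list[DuplexRecord], int]:
    """profile -> designate -> filter, for a whole cohort.

    Returns (filtered duplexes in record order, unmatched read tally).
    """
    records = list(records)
    profiles, unmatched = profile_isoforms(library, records, arm_window=arm_window)
    by_hid: dict[str, list[IsoformProfile]] = {}
    for p in profiles:
        by_hid.setdefault(p.hairpin_id, []).append(p)
    duplexes = []
    for rec in records:
        d = designate_strands(by_hid.get(rec.id, []))
        if d is not None:
            duplexes.append(d)
    return filter_expressed(duplexes, min_reads=min_reads, per_strand=per_strand), unmatched
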