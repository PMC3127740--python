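"""Synthetic hairpin/library cohorts with a ground-truth ledger.

Each synthetic hairpin embeds a miRNA and a miRNA* arm (the star strand is
built complementary-with-mismatches to the miRNA, with a 2-nt 3' overhang),
joined by a loop and padded to the requested hairpin length.  Read libraries
realize a per-hairpin depth law, an asymmetry law over the miRNA:miRNA*
ratio, and 5'-end isoform jitter.  An optional injection makes the identity
of a chosen position statistically dependent on miRNA nt 1, giving the
covariation scan a known signal to recover.  Every sampled quantity is
recorded in the truth ledger.  All output is bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .annotation_io import (
    PreMirnaRecord,
    ReadLibrary,
    write_annotations,
    write_tag_counts,
)

NUCLEOTIDES = ("A", "C", "G", "U")
_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

__all__ = [
    "SyntheticParams",
    "CovariationInjection",
    "generate_cohort",
    "write_cohort",
]


@dataclass
class CovariationInjection:
    """Make the nucleotide at ``(strand, position)`` depend on miRNA nt 1."""

    strand: str = "miRNA"  # miRNA | miRNA*
    position: int = 2  # 1-based from the strand 5' end
    given_nt1: str = "U"
    dist_match: tuple = (0.0333, 0.0333, 0.0334, 0.9)  # when nt1 == given_nt1
    dist_other: tuple = (0.25, 0.25, 0.25, 0.25)


@dataclass
class SyntheticParams:
    n_hairpins: int = 50
    hairpin_len: int = 64
    mature_len: int = 22
    loop_len: int = 15
    body_nt_probs: tuple = (0.25, 0.25, 0.25, 0.25)
    mirna_nt1_probs: tuple = (0.25, 0.25, 0.25, 0.25)
    star_nt1_probs: tuple = (0.25, 0.25, 0.25, 0.25)
    # distribution laws: ("constant", v) | ("uniform", lo, hi) | ("lognormal", median, sigma)
    asymmetry_law: tuple = ("lognormal", 5.0, 1.0)
    depth_law: tuple = ("lognormal", 300.0, 1.0)
    isoform_jitter: float = 0.0
    covariation_injection: Optional[CovariationInjection] = None
    complementarity: float = 0.9
    species: str = "syn"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hairpins < 1:
            raise ValueError("n_hairpins must be >= 1")
        if self.mature_len >= self.hairpin_len / 2:
            raise ValueError("mature_len must be < hairpin_len / 2")
        star_len = self.mature_len - 1
        if self.mature_len + self.loop_len + star_len > self.hairpin_len:
            raise ValueError("arms plus loop exceed hairpin_len")
        for name in ("body_nt_probs", "mirna_nt1_probs", "star_nt1_probs"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (4,) or not np.isclose(v.sum(), 1.0) or np.any(v < 0):
                raise ValueError(f"{name} must be a probability 4-vector")
        if not 0.0 <= self.isoform_jitter <= 1.0:
            raise ValueError("isoform_jitter must be in [0, 1]")
        if not 0.0 <= self.complementarity <= 1.0:
            raise ValueError("complementarity must be in [0, 1]")


def _draw(law: tuple, rng: np.random.Generator, minimum: float = 0.0) -> float:
    kind = law[0]
    if kind == "constant":
        x = float(law[1])
    elif kind == "uniform":
        x = float(rng.uniform(law[1], law[2]))
    elif kind == "lognormal":
        median, sigma = float(law[1]), float(law[2])
        x = float(np.exp(np.log(median) + sigma * rng.standard_normal()))
    else:
        raise ValueError(f"unknown law {law!r}")
    return max(x, minimum)


def _sample_seq(rng: np.random.Generator, n: int, probs) -> list[str]:
    idx = rng.choice(4, size=n, p=np.asarray(probs, dtype=float))
    return [NUCLEOTIDES[i] for i in idx]


def generate_cohort(
    params: SyntheticParams,
) -> tuple[list[PreMirnaRecord], ReadLibrary, pd.DataFrame]:
    """Sample a cohort: (hairpin records, pooled read library, truth ledger)."""
    rng = np.random.default_rng(params.seed)
    L = params.mature_len
    star_len = L - 1

    records: list[PreMirnaRecord] = []
    counts: dict[str, int] = {}
    truth_rows = []

    for h in range(params.n_hairpins):
        hid = f"syn-mir-{h + 1}"
        # --- miRNA sequence
        mirna = _sample_seq(rng, L, params.body_nt_probs)
        mirna[0] = _sample_seq(rng, 1, params.mirna_nt1_probs)[0]
        inj = params.covariation_injection
        if inj is not None and inj.strand == "miRNA":
            dist = inj.dist_match if mirna[0] == inj.given_nt1 else inj.dist_other
            mirna[inj.position - 1] = _sample_seq(rng, 1, dist)[0]
        # --- star: complementary-with-mismatches, 2-nt 3' overhangs on both
        # strands: star[j] (1-based) pairs miRNA[i] with i + j = star_len - 1,
        # so miRNA nt 1 pairs star position star_len - 2.
        star = []
        for j in range(1, star_len + 1):
            partner = star_len - 1 - j  # 1-based miRNA position; <1 means overhang
            if partner >= 1 and rng.random() < params.complementarity:
                star.append(_COMPLEMENT[mirna[partner - 1]])
            else:
                star.append(_sample_seq(rng, 1, params.body_nt_probs)[0])
        star[0] = _sample_seq(rng, 1, params.star_nt1_probs)[0]
        if inj is not None and inj.strand == "miRNA*":
            dist = inj.dist_match if mirna[0] == inj.given_nt1 else inj.dist_other
            star[inj.position - 1] = _sample_seq(rng, 1, dist)[0]
        mirna_seq = "".join(mirna)
        star_seq = "".join(star)

        # --- hairpin assembly
        mirna_arm = "5p" if rng.random() < 0.5 else "3p"
        arm5p_seq, arm3p_seq = (
            (mirna_seq, star_seq) if mirna_arm == "5p" else (star_seq, mirna_seq)
        )
        loop = "".join(_sample_seq(rng, params.loop_len, params.body_nt_probs))
        pad = params.hairpin_len - len(arm5p_seq) - params.loop_len - len(arm3p_seq)
        f5 = pad // 2
        f3 = pad - f5
        flank5 = "".join(_sample_seq(rng, f5, params.body_nt_probs))
        flank3 = "".join(_sample_seq(rng, f3, params.body_nt_probs))
        hairpin = flank5 + arm5p_seq + loop + arm3p_seq + flank3
        a5_start = f5 + 1
        a5_end = f5 + len(arm5p_seq)
        a3_start = a5_end + params.loop_len + 1
        a3_end = a3_start + len(arm3p_seq) - 1
        rec = PreMirnaRecord(
            id=hid,
            hairpin_seq=hairpin,
            species=params.species,
            arm5p_start=a5_start,
            arm5p_end=a5_end,
            arm3p_start=a3_start,
            arm3p_end=a3_end,
        )
        records.append(rec)

        # --- read counts
        total = max(1, int(round(_draw(params.depth_law, rng, minimum=1.0))))
        # reflect sub-unity draws: the miRNA is the more abundant strand by
        # definition, and reflection avoids an atom at ratio exactly 1
        ratio = _draw(params.asymmetry_law, rng, minimum=0.0)
        if 0 < ratio < 1.0:
            ratio = 1.0 / ratio
        ratio = max(ratio, 1.0)
        mirna_count = int(round(total * ratio / (1.0 + ratio)))
        mirna_count = min(max(mirna_count, total - mirna_count), total)
        star_count = total - mirna_count
        if ratio > 1.0 and mirna_count == star_count:
            mirna_count += 1  # rounding tie: keep the designated strand on top
            star_count -= 1

        for arm, strand_count in (
            (mirna_arm, mirna_count),
            ("3p" if mirna_arm == "5p" else "5p", star_count),
        ):
            if strand_count == 0:
                continue
            start, end = rec.arm_bounds(arm)
            n_shift = rng.binomial(strand_count, params.isoform_jitter)
            shifts = [0] * (strand_count - n_shift)
            if n_shift:
                shifts.extend(int(s) for s in rng.choice([-2, -1, 1, 2], size=n_shift))
            tag_counts: dict[str, int] = {}
            length = end - start + 1
            for s in shifts:
                a = start + s
                b = a + length - 1
                if a < 1 or b > len(hairpin):
                    a, b = start, end  # shift would leave the hairpin: keep canonical
                tag = hairpin[a - 1 : b]
                tag_counts[tag] = tag_counts.get(tag, 0) + 1
            for tag, c in tag_counts.items():
                counts[tag] = counts.get(tag, 0) + c

        truth_rows.append(
            {
                "hairpin_id": hid,
                "mirna_arm": mirna_arm,
                "mirna_seq": mirna_seq,
                "star_seq": star_seq,
                "mirna_nt1": mirna_seq[0],
                "star_nt1": star_seq[0],
                "true_ratio": ratio,
                "total_reads": total,
                "mirna_count": mirna_count,
                "star_count": star_count,
                "injected": "" if inj is None else f"{inj.strand}:{inj.position}",
            }
        )

    library = ReadLibrary(source_ids=[f"synthetic-seed{params.seed}"], counts=counts)
    return records, library, pd.DataFrame(truth_rows)


def write_cohort(
    records: list[PreMirnaRecord],
    library: ReadLibrary,
    truth: pd.DataFrame,
    outdir,
) -> dict[str, Path]:
    """Write FASTA + coordinate TSV + tag-count TSV + truth ledger TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hairpins": outdir / "hairpins.fa",
        "coords": outdir / "arms.tsv",
        "reads": outdir / "reads.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_annotations(records, paths["hairpins"], paths["coords"])
    write_tag_counts(library, paths["reads"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
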