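"""End-to-end orchestration: quantify -> composition (per stratum) ->
duplex structure -> covariation -> flanking profile, with TSV reports and a
run manifest.  All randomness flows from the config seed; reruns with the
same config produce byte-identical reports."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotation_io import pool_libraries, read_annotations, read_tag_counts
from .composition import (
    MIRNA,
    NUCLEOTIDES,
    STAR,
    analyze_composition,
    flanking_u_profile,
)
from .config import PipelineConfig
from .covariation import build_feature_vector, covariation_scan, scan_to_frame
from .duplex_structure import (
    ScoreModel,
    extract_duplex,
    pair_probabilities,
    pairing_status,
)
from .quantify import BINS, build_duplexes

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _strata(config: PipelineConfig, duplexes):
    wanted = [s.strip() for s in config.strata.split(",") if s.strip()]
    out = [("all", None)]
    if "by_arm" in wanted:
        out += [
            ("arm_5p", lambda d: d.mirna_arm == "5p"),
            ("arm_3p", lambda d: d.mirna_arm == "3p"),
        ]
    if "by_bin" in wanted:
        out += [(f"bin_{b}", (lambda b: lambda d: d.bin == b)(b)) for b in BINS]
    if "all" not in wanted:
        out = out[1:]
    return out


def run_pipeline(config: PipelineConfig, records=None, library=None) -> dict:
    """Run every stage; returns {report name: path}.  ``records``/``library``
    may be passed directly (e.g. from the synthetic generator) instead of
    being read from the configured input paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    if records is None:
        if config.hairpin_fasta is None or config.mature_coords is None:
            raise ValueError("hairpin_fasta and mature_coords are required")
        records = read_annotations(config.hairpin_fasta, config.mature_coords)
    if library is None:
        if not config.tag_counts:
            raise ValueError("at least one tag_counts file is required")
        library = pool_libraries(
            [read_tag_counts(p, dialect=config.tag_dialect) for p in config.tag_counts]
        )

    # ---- quantify
    duplexes, unmatched = build_duplexes(
        library,
        records,
        arm_window=config.arm_window,
        min_reads=config.min_reads,
        per_strand=config.min_reads_per_strand,
    )
    logger.info(
        "quantify: %d duplexes pass (>=%d reads); %d unmatched reads",
        len(duplexes), config.min_reads, unmatched,
    )
    rec_by_id = {r.id: r for r in records}
    dup_rows = []
    for d in duplexes:
        rec = rec_by_id[d.hairpin_id]
        dup_rows.append(
            {
                "hairpin_id": d.hairpin_id,
                "mirna_arm": d.mirna_arm,
                "mirna_seq": d.mirna_profile.top_isoform(rec.arm_bounds(d.mirna_arm)[0])[0],
                "star_seq": (
                    d.star_profile.top_isoform(rec.arm_bounds(d.star_arm)[0])[0]
                    if d.star_profile.isoforms else ""
                ),
                "mirna_count": d.mirna_count,
                "star_count": d.star_count,
                "ratio": d.ratio,
                "bin": d.bin,
            }
        )
    paths = {"duplexes": outdir / "duplexes.tsv"}
    pd.DataFrame(dup_rows).to_csv(paths["duplexes"], sep="\t", index=False)

    # ---- composition per stratum and strand class
    comp_rows = []
    for stratum, flt in _strata(config, duplexes):
        for strand_class in (MIRNA, STAR):
            try:
                res = analyze_composition(
                    duplexes,
                    strand_class=strand_class,
                    stratum=stratum,
                    stratum_filter=flt,
                    n_sets=config.n_sets,
                    window=(config.window_start, config.window_end),
                    rng=rng,
                    two_sided=config.two_sided,
                )
            except ValueError as exc:
                logger.info("composition: stratum %s/%s skipped (%s)", stratum, strand_class, exc)
                continue
            for k, nt in enumerate(NUCLEOTIDES):
                comp_rows.append(
                    {
                        "stratum": stratum,
                        "strand_class": strand_class,
                        "nucleotide": nt,
                        "observed_freq": res.observed_freq[k],
                        "resample_mean": res.resample_mean[k],
                        "resample_sd": res.resample_sd[k],
                        "p_empirical": res.p_empirical[k],
                        "p_gaussian": res.p_gaussian[k],
                    }
                )
    paths["composition"] = outdir / "composition.tsv"
    pd.DataFrame(comp_rows).to_csv(paths["composition"], sep="\t", index=False, float_format="%.10g")

    # ---- duplex structure + covariation
    model = ScoreModel(
        gc=config.score_gc, au=config.score_au, gu=config.score_gu,
        run_penalty=config.run_penalty, asym_penalty=config.asym_penalty,
    )
    struct_rows = []
    fvs = []
    for d in duplexes:
        rec = rec_by_id[d.hairpin_id]
        try:
            arm_profiles = {
                d.mirna_arm: d.mirna_profile,
                d.star_arm: d.star_profile,
            }
            seq5, seq3 = extract_duplex(rec, arm_profiles)
        except ValueError as exc:
            logger.info("structure: %s skipped (%s)", d.hairpin_id, exc)
            continue
        mirna_seq, star_seq = (seq5, seq3) if d.mirna_arm == "5p" else (seq3, seq5)
        matrix = pair_probabilities(mirna_seq, star_seq, engine=config.engine, model=model)
        status = pairing_status(matrix, threshold=config.pairing_threshold)
        fvs.append(build_feature_vector(d.hairpin_id, mirna_seq, star_seq, status))
        for strand, seq, paired, partner, p_tot in (
            ("miRNA", mirna_seq, status.paired_a, status.partner_a, matrix.p.sum(axis=1)),
            ("miRNA*", star_seq, status.paired_b, status.partner_b, matrix.p.sum(axis=0)),
        ):
            for i, nt in enumerate(seq):
                struct_rows.append(
                    {
                        "hairpin_id": d.hairpin_id,
                        "strand": strand,
                        "position": i + 1,
                        "nucleotide": nt,
                        "p_paired": p_tot[i],
                        "paired_call": bool(paired[i]),
                        "partner": partner[i] if partner[i] is not None else "",
                    }
                )
    paths["structure"] = outdir / "structure.tsv"
    pd.DataFrame(struct_rows).to_csv(paths["structure"], sep="\t", index=False, float_format="%.10g")

    nt1_levels = {fv.nt1 for fv in fvs}
    if len(nt1_levels) >= 2:
        results = covariation_scan(
            fvs,
            method=config.fisher_method,
            n_mc=config.fisher_n_mc,
            seed=int(rng.integers(2**31)),
            enumeration_cap=config.enumeration_cap,
            collapse_nt1_u=config.collapse_nt1_u,
        )
        scan_df = scan_to_frame(results)
    else:
        logger.warning("covariation: constant nt1, scan skipped")
        scan_df = pd.DataFrame()
    paths["covariation"] = outdir / "covariation.tsv"
    scan_df.to_csv(paths["covariation"], sep="\t", index=False, float_format="%.10g")

    # ---- flanking profile
    try:
        prof = flanking_u_profile(
            records, duplexes,
            halfwidth=config.flank_halfwidth,
            n_sets=config.n_sets,
            ci=config.flank_ci,
            rng=rng,
        )
        flank_df = pd.DataFrame(
            {
                "offset": prof.offsets,
                "u_freq": prof.u_freq,
                "background_mean": prof.background_mean,
                "ci_low": prof.ci_low,
                "ci_high": prof.ci_high,
            }
        )
    except ValueError as exc:
        logger.warning("flanking profile skipped (%s)", exc)
        flank_df = pd.DataFrame()
    paths["flanking"] = outdir / "flanking.tsv"
    flank_df.to_csv(paths["flanking"], sep="\t", index=False, float_format="%.10g")

    # ---- manifest
    manifest = {
        "mirasym_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "n_records": len(records),
        "n_duplexes": len(duplexes),
        "unmatched_reads": unmatched,
    }
    paths["manifest"] = outdir / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return paths
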