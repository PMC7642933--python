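"""Readers/writers for panel, count, abundance and sample-sheet tables.

All tabular artifacts are tab-separated text with a header row; lines
starting with '#' are comments (every writer emits a comment header naming
the tool version and the resolved parameters, so each file records how it
was made). Gzip input is handled transparently by extension.
"""

from __future__ import annotations

import gzip
import io as _io
import json
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .probe_design import MipProbe, ProbePanel, StrainVariant

SAMPLE_SHEET_COLUMNS = ["library_id", "pool_id", "replicate_id", "condition",
                        "generation"]

PANEL_COLUMNS = ["probe_id", "strain_id", "chrom", "pos", "ref", "alt",
                 "ext_arm", "lig_arm", "gap_fill_seq", "gap_fill_start",
                 "snv_offset", "score"]


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def write_tsv(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a DataFrame as TSV with a '#' provenance header."""
    with _open_text(path, "wt") as fh:
        fh.write(f"# mipfit {__version__}\n")
        if params:
            fh.write(f"# params: {json.dumps(params, sort_keys=True)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    with _open_text(path) as fh:
        return pd.read_csv(fh, sep="\t", comment="#", **kwargs)


def write_panels(panels: dict[str, ProbePanel], path, params: dict | None = None) -> None:
    write_tsv(panels_to_frame(panels), path, params)


def panels_to_frame(panels: dict[str, ProbePanel]) -> pd.DataFrame:
    rows = []
    for strain_id in sorted(panels):
        for p in panels[strain_id].probes:
            rows.append((p.probe_id, p.strain_id, p.target.chrom, p.target.pos,
                         p.target.ref_allele, p.target.alt_allele, p.ext_arm_seq,
                         p.lig_arm_seq, p.gap_fill_seq, p.gap_fill_start,
                         p.snv_offset, p.score))
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def read_panels(path) -> dict[str, ProbePanel]:
    """Round-trip a panel TSV back into ProbePanel objects."""
    df = read_tsv(path, dtype={"chrom": str})
    return frame_to_panels(df)


def frame_to_panels(df: pd.DataFrame) -> dict[str, ProbePanel]:
    panels: dict[str, ProbePanel] = {}
    for row in df.itertuples():
        target = StrainVariant(row.strain_id, str(row.chrom), int(row.pos),
                               row.ref, row.alt)
        probe = MipProbe(
            probe_id=row.probe_id, strain_id=row.strain_id, target=target,
            ext_arm_seq=row.ext_arm, lig_arm_seq=row.lig_arm,
            gap_fill_seq=row.gap_fill_seq, gap_fill_start=int(row.gap_fill_start),
            snv_offset=int(row.snv_offset), score=float(row.score),
        )
        panels.setdefault(row.strain_id, ProbePanel(row.strain_id, [])).probes.append(probe)
    return panels


def panel_frame_for_quantify(panels: dict[str, ProbePanel]) -> pd.DataFrame:
    """Panel table in the column layout quantify.parse_reads expects."""
    df = panels_to_frame(panels)
    df["gap_fill_len"] = df["gap_fill_seq"].str.len()
    return df


def read_sample_sheet(path) -> pd.DataFrame:
    """Read and validate a sample sheet; raises on structural problems."""
    df = read_tsv(path, dtype={"library_id": str, "condition": str})
    errors = validate_sample_sheet(df)
    if errors:
        raise ValueError("; ".join(errors))
    return df


def validate_sample_sheet(df: pd.DataFrame) -> list[str]:
    errors = []
    for col in SAMPLE_SHEET_COLUMNS:
        if col not in df.columns:
            errors.append(f"sample sheet missing column: {col}")
    if errors:
        return errors
    dup = df["library_id"][df["library_id"].duplicated()]
    if len(dup):
        errors.append(f"duplicated library_id: {sorted(set(dup))}")
    if (df["generation"] < 0).any():
        errors.append("generation must be >= 0")
    return errors


def read_strain_variants(vcf_path, strain_id: str | None = None) -> list[StrainVariant]:
    """Read SNVs from a VCF into StrainVariant records.

    Multi-sample VCF: each sample carrying a non-reference genotype at a
    biallelic SNV yields one record (strain = sample name). Sites-only or
    single-sample VCF with ``strain_id`` given: every SNV is assigned to
    that strain. Non-SNV records are skipped.
    """
    import pysam

    variants: list[StrainVariant] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if len(rec.ref) != 1 or len(alt) != 1 or alt not in "ACGT":
                    continue
                if samples and strain_id is None:
                    for sample in samples:
                        gt = rec.samples[sample].get("GT", ())
                        alt_index = rec.alts.index(alt) + 1
                        if gt and alt_index in gt:
                            variants.append(StrainVariant(sample, rec.chrom, rec.pos,
                                                          rec.ref, alt))
                else:
                    sid = strain_id or "sample"
                    variants.append(StrainVariant(sid, rec.chrom, rec.pos, rec.ref, alt))
    return variants


def validate_inputs(panels: dict[str, ProbePanel] | None = None,
                    reference=None,
                    counts: pd.DataFrame | None = None,
                    sheet: pd.DataFrame | None = None) -> list[str]:
    """Cross-check inputs; returns a list of all problems found (empty = clean).

    Checks: panel ref allele matches the reference base at the target
    position; every library in a counts table appears in the sample sheet;
    sample-sheet structure.
    """
    report: list[str] = []
    if panels is not None and reference is not None:
        from .probe_design import _fetch

        for panel in panels.values():
            for p in panel.probes:
                try:
                    base = _fetch(reference, p.target.chrom, p.target.pos - 1,
                                  p.target.pos)
                except (KeyError, ValueError):
                    report.append(f"contig {p.target.chrom} missing from reference "
                                  f"(probe {p.probe_id})")
                    continue
                if base != p.target.ref_allele:
                    report.append(
                        f"panel ref mismatch at {p.target.chrom}:{p.target.pos}: "
                        f"panel says {p.target.ref_allele}, reference has {base}"
                    )
    if sheet is not None:
        report.extend(validate_sample_sheet(sheet))
        if counts is not None and not sheet.empty:
            known = set(sheet["library_id"])
            for lib in sorted(set(counts["library_id"]) - known):
                report.append(f"counts reference unknown library_id: {lib}")
    return report


def write_manifest(path, stage_status: dict[str, str], params: dict) -> None:
    """Machine-readable record of one pipeline invocation."""
    manifest = {
        "tool": f"mipfit {__version__}",
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "params": params,
        "stages": stage_status,
        "complete": all(v == "ok" for v in stage_status.values()),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
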