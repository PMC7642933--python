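"""Turn MIP sequencing reads into UMI-deduplicated strain abundances.

A capture event is one probe annealing observation identified by its unique
molecular identifier (UMI); after deduplication each distinct UMI counts
once. The base observed at the target SNV position inside the gap-fill
classifies the event as ALT (the strain-private variant), REF (reference
base) or OTHER. Per-probe abundance is ALT/(ALT+REF); strain abundance is
the unweighted mean of the strain's QC-passing probes, with a sample
standard deviation across them.

False-positive behaviour is estimated from probes whose target strain is
known to be absent from the genomic template: every ALT event for such a
probe is a miscall. The detection limit is the per-probe mean false-positive
rate plus ``k_sd`` standard deviations (default five).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

ALT, REF, OTHER = "ALT", "REF", "OTHER"

COUNT_COLUMNS = ["library_id", "probe_id", "alt_umis", "ref_umis", "other_umis",
                 "total_umis", "discarded_ties"]


@dataclass
class ReadLayout:
    """How a sequencing read maps onto a probe.

    Reads are single-end, plus strand: [extension arm][gap-fill][ligation
    arm]. The UMI lives either in the read name (last colon-separated
    field, ``umi_source='header'``) or inline immediately after the
    ligation arm (``umi_source='inline'``).
    """

    umi_len: int = 8
    umi_source: str = "header"  # 'header' | 'inline'
    arm_match_max_mismatch: int = 0
    orientation: str = "ext-first"

    def __post_init__(self):
        if self.umi_len <= 0:
            raise ValueError("umi_len must be positive")
        if self.arm_match_max_mismatch < 0:
            raise ValueError("mismatch tolerance must be >= 0")
        if self.umi_source not in ("header", "inline"):
            raise ValueError(f"unknown umi_source {self.umi_source!r}")


@dataclass(frozen=True)
class CaptureEvent:
    probe_id: str
    umi: str
    allele_call: str  # ALT | REF | OTHER


@dataclass
class FprEstimate:
    """Per-event and per-probe false-positive rates from absent-strain probes."""

    per_event_rate: float
    per_probe_mean: float
    per_probe_sd: float
    k_sd: int = 5
    n_events: int = 0

    @property
    def detection_limit(self) -> float:
        return self.per_probe_mean + self.k_sd * self.per_probe_sd


@dataclass
class _ProbeRef:
    """Per-probe matching info derived from a panel table row."""

    probe_id: str
    strain_id: str
    ext_arm: str
    lig_arm: str
    gap_fill_len: int
    snv_offset: int
    ref_allele: str
    alt_allele: str


def _probe_refs(panel_df: pd.DataFrame) -> list[_ProbeRef]:
    return [
        _ProbeRef(
            probe_id=row.probe_id,
            strain_id=row.strain_id,
            ext_arm=row.ext_arm,
            lig_arm=row.lig_arm,
            gap_fill_len=int(row.gap_fill_len),
            snv_offset=int(row.snv_offset),
            ref_allele=row.ref,
            alt_allele=row.alt,
        )
        for row in panel_df.itertuples()
    ]


def _mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                break
    return n


def parse_reads(reads, panel_df: pd.DataFrame, layout: ReadLayout | None = None):
    """Assign reads to probes and classify the allele at the target SNV.

    ``reads`` is a FASTQ path (gz allowed) or an iterable of ``(name, seq)``
    pairs. A read is assigned to the unique probe whose extension and
    ligation arms both match within ``arm_match_max_mismatch``; ambiguous
    (multi-probe) and unassignable reads are dropped and counted.

    Returns ``(events, stats)`` where stats counts assigned / unassigned /
    ambiguous / truncated reads.
    """
    layout = layout or ReadLayout()
    probes = _probe_refs(panel_df)
    events: list[CaptureEvent] = []
    stats = Counter(assigned=0, unassigned=0, ambiguous=0, truncated=0)
    for name, seq in _iter_reads(reads):
        seq = seq.upper()
        hits = []
        truncated = False
        for p in probes:
            need = len(p.ext_arm) + p.gap_fill_len + len(p.lig_arm)
            if layout.umi_source == "inline":
                need += layout.umi_len
            if len(seq) < need:
                truncated = True
                continue
            lig_start = len(p.ext_arm) + p.gap_fill_len
            if (_mismatches(seq[:len(p.ext_arm)], p.ext_arm, layout.arm_match_max_mismatch)
                    <= layout.arm_match_max_mismatch
                    and _mismatches(seq[lig_start:lig_start + len(p.lig_arm)], p.lig_arm,
                                    layout.arm_match_max_mismatch)
                    <= layout.arm_match_max_mismatch):
                hits.append(p)
        if len(hits) == 1:
            p = hits[0]
            base = seq[len(p.ext_arm) + p.snv_offset]
            call = ALT if base == p.alt_allele else REF if base == p.ref_allele else OTHER
            if layout.umi_source == "inline":
                tail = len(p.ext_arm) + p.gap_fill_len + len(p.lig_arm)
                umi = seq[tail:tail + layout.umi_len]
            else:
                umi = name.rsplit(":", 1)[-1]
            events.append(CaptureEvent(p.probe_id, umi, call))
            stats["assigned"] += 1
        elif len(hits) > 1:
            stats["ambiguous"] += 1
        elif truncated:
            stats["truncated"] += 1
        else:
            stats["unassigned"] += 1
    return events, dict(stats)


def _iter_reads(reads):
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        import pysam

        with pysam.FastxFile(str(reads)) as fh:
            for rec in fh:
                name = rec.name if rec.comment is None else f"{rec.name} {rec.comment}"
                yield name, rec.sequence
    else:
        yield from reads


def dedup_umis(events, library_id: str = "lib") -> pd.DataFrame:
    """Collapse capture events to one count per distinct (probe, UMI).

    A UMI observed with conflicting allele calls is assigned by majority
    vote; exact ties are discarded (counted in ``discarded_ties``). The
    result is invariant to read order.
    """
    calls: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for ev in events:
        calls[(ev.probe_id, ev.umi)][ev.allele_call] += 1
    tallies: dict[str, Counter] = defaultdict(Counter)
    for (probe_id, _umi), votes in calls.items():
        top = votes.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            tallies[probe_id]["ties"] += 1
        else:
            tallies[probe_id][top[0][0]] += 1
    rows = []
    for probe_id in sorted(tallies):
        t = tallies[probe_id]
        alt, ref, other = t[ALT], t[REF], t[OTHER]
        rows.append((library_id, probe_id, alt, ref, other, alt + ref + other, t["ties"]))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def probe_abundance(alt_umis: int, ref_umis: int) -> float:
    """ALT fraction among diagnostic events; OTHER calls are excluded from
    the denominator. NaN when no diagnostic event was seen."""
    denom = alt_umis + ref_umis
    if denom == 0:
        return float("nan")
    return alt_umis / denom


def library_qc(counts: pd.DataFrame, min_fraction: float = 0.20):
    """Flag under-performing probes; drop those failing in *every* library.

    Within each library a probe is flagged when its total UMI count falls
    below ``min_fraction`` of that library's mean per-probe total. Only
    probes flagged consistently — in all libraries — are removed.

    Returns ``(retained_probe_ids, flags)`` where ``flags`` is a boolean
    DataFrame indexed by probe with one column per library.
    """
    pivot = counts.pivot_table(index="probe_id", columns="library_id",
                               values="total_umis", aggfunc="sum", fill_value=0)
    flags = pivot.lt(min_fraction * pivot.mean(axis=0), axis=1)
    removed = flags.all(axis=1)
    retained = set(pivot.index[~removed])
    return retained, flags


def strain_abundance(counts: pd.DataFrame, probe_to_strain: dict[str, str],
                     retained=None) -> pd.DataFrame:
    """Per (library, strain): mean and sample SD of probe ALT fractions.

    Probes outside ``retained`` (when given) or with no diagnostic events
    are skipped; a strain with no usable probe in a library is reported
    missing (absent row). Single-probe strains get sd 0 with ``sd_defined``
    False.
    """
    rows = []
    for (library_id, strain_id), grp in counts.assign(
            strain_id=counts["probe_id"].map(probe_to_strain)).groupby(
            ["library_id", "strain_id"], sort=True):
        fracs = []
        for row in grp.itertuples():
            if retained is not None and row.probe_id not in retained:
                continue
            f = probe_abundance(row.alt_umis, row.ref_umis)
            if not math.isnan(f):
                fracs.append(f)
        if not fracs:
            continue
        sd = float(np.std(fracs, ddof=1)) if len(fracs) > 1 else 0.0
        rows.append((library_id, strain_id, float(np.mean(fracs)), sd,
                     len(fracs), len(fracs) > 1))
    return pd.DataFrame(rows, columns=["library_id", "strain_id", "mean_abundance",
                                       "sd_abundance", "n_probes_used", "sd_defined"])


def estimate_fpr(counts: pd.DataFrame, probe_to_strain: dict[str, str],
                 absent_strains: dict[str, set], k_sd: int = 5) -> FprEstimate:
    """Estimate the false-positive rate from probes of template-absent strains.

    ``absent_strains`` maps library_id -> strains provably absent from that
    library's genomic template; every ALT event on their probes is a
    miscall. The per-event rate pools all such probes; the per-probe mean
    and sample SD summarise the spread of per-(library, probe) rates.
    """
    if not absent_strains or all(not s for s in absent_strains.values()):
        raise ValueError("no absent strains declared; cannot estimate FPR")
    alt_sum = 0
    total_sum = 0
    per_probe_rates = []
    for row in counts.itertuples():
        absent = absent_strains.get(row.library_id, set())
        if probe_to_strain.get(row.probe_id) in absent and row.total_umis > 0:
            alt_sum += row.alt_umis
            total_sum += row.total_umis
            per_probe_rates.append(row.alt_umis / row.total_umis)
    if total_sum == 0:
        raise ValueError("no capture events observed for absent strains")
    sd = float(np.std(per_probe_rates, ddof=1)) if len(per_probe_rates) > 1 else 0.0
    return FprEstimate(
        per_event_rate=alt_sum / total_sum,
        per_probe_mean=float(np.mean(per_probe_rates)),
        per_probe_sd=sd,
        k_sd=k_sd,
        n_events=int(total_sum),
    )


def detection_limit(estimate: FprEstimate) -> float:
    """Minimum trustworthy abundance: mean FPR plus k standard deviations."""
    return estimate.detection_limit
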