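"""Design strain-identifying molecular inversion probe (MIP) panels.

Each pooled strain is tracked through strain-private SNVs: single-base
substitutions carried by exactly one strain in the pooled set, so that the
base filled in between the two probe arms acts as a barcode for that strain.
Site selection enforces a minimum spacing between accepted sites so that
neighbouring probes cannot collide, and an exclusion window keeps a second
round of candidates (e.g. wild-isolate sites) away from sites already
reserved in a first round.

Panel assembly mirrors a two-stage choice: the best-scoring probe per
chromosome is identified for every strain, and a fixed-size panel (default
four probes) is then drawn at random from those per-chromosome winners so
that each strain is tracked on several linkage groups.
"""

from __future__ import annotations

import logging
import re
import zlib
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_DNA_BASES = frozenset("ACGT")

# C. elegans karyotype; unknown contigs sort after, alphabetically.
_KARYOTYPE = {"I": 0, "II": 1, "III": 2, "IV": 3, "V": 4, "X": 5, "MtDNA": 6}


def karyotype_key(chrom: str):
    """Sort key placing nuclear linkage groups in karyotype order."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name in _KARYOTYPE:
        return (0, _KARYOTYPE[name], "")
    return (1, 0, name)


@dataclass(frozen=True, order=True)
class StrainVariant:
    """One strain-private SNV usable as a barcode site (1-based position)."""

    strain_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"SNVs only: {self.ref_allele}>{self.alt_allele}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")


@dataclass
class ScoringWeights:
    """Relative weights of the four default probe-scoring terms."""

    gc: float = 1.0
    tm: float = 1.0
    homopolymer: float = 1.0
    centrality: float = 1.0


@dataclass
class DesignParams:
    """Tunable knobs of panel design.

    min_spacing_bp: minimum distance between any two accepted sites genome-wide.
    exclusion_window_bp: candidates within this distance of a reserved site
        (centre-to-centre) are discarded.
    panel_size: probes retained per strain.
    candidates_per_strain: per-chromosome winners the panel is drawn from
        (one per chromosome; six for the six C. elegans linkage groups).
    """

    min_spacing_bp: int = 300
    exclusion_window_bp: int = 350
    panel_size: int = 4
    candidates_per_strain: int = 6
    rng_seed: int = 0
    ext_arm_len: int = 20
    lig_arm_len: int = 20
    gap_fill_len: int = 100
    snv_offset_step: int = 10
    weights: ScoringWeights = field(default_factory=ScoringWeights)

    def __post_init__(self):
        if not (0 < self.panel_size <= self.candidates_per_strain):
            raise ValueError("require 0 < panel_size <= candidates_per_strain")
        if self.min_spacing_bp <= 0:
            raise ValueError("min_spacing_bp must be positive")


@dataclass
class MipProbe:
    """A designed probe: two annealing arms flanking a gap-fill interval.

    Genomic coordinates are 0-based half-open internally; ``target.pos``
    stays 1-based as in VCF. ``snv_offset`` is the 0-based offset of the
    target SNV within the gap-fill, and ``gap_fill_seq`` is the reference
    sequence of the gap-fill (the ALT read differs at ``snv_offset``).
    """

    probe_id: str
    strain_id: str
    target: StrainVariant
    ext_arm_seq: str
    lig_arm_seq: str
    gap_fill_seq: str
    gap_fill_start: int  # 0-based genomic start of the gap-fill
    snv_offset: int
    score: float

    @property
    def gap_fill_len(self) -> int:
        return len(self.gap_fill_seq)


@dataclass
class ProbePanel:
    """The probe set identifying one strain."""

    strain_id: str
    probes: list[MipProbe]


def remove_shared_variants(variants) -> list[StrainVariant]:
    """Keep only variants whose (chrom, pos, alt) occurs in exactly one strain.

    A site shared by two strains cannot distinguish them, so it is dropped
    from every strain. Input order is preserved for the survivors.
    """
    variants = list(variants)
    owners: dict[tuple, set[str]] = {}
    for v in variants:
        owners.setdefault((v.chrom, v.pos, v.alt_allele), set()).add(v.strain_id)
    return [v for v in variants if len(owners[(v.chrom, v.pos, v.alt_allele)]) == 1]


def _check_sorted(variants) -> None:
    for a, b in zip(variants, variants[1:]):
        ka, kb = (karyotype_key(a.chrom), a.pos), (karyotype_key(b.chrom), b.pos)
        if ka > kb:
            raise ValueError(
                "variants must be sorted by (chrom, pos); "
                f"{a.chrom}:{a.pos} precedes {b.chrom}:{b.pos}"
            )


def sort_variants(variants) -> list[StrainVariant]:
    """Sort by karyotype chromosome order then position (the mandated scan order)."""
    return sorted(variants, key=lambda v: (karyotype_key(v.chrom), v.pos))


def select_spaced_sites(variants, min_spacing_bp: int) -> list[StrainVariant]:
    """Greedy linear scan per chromosome: accept the first available site,
    then every subsequent site at least ``min_spacing_bp`` downstream of the
    last accepted one (sites exactly at the spacing are accepted).

    The scan runs genome-wide across all strains jointly, so accepted sites
    of different strains also respect the spacing. Input must be sorted;
    unsorted input raises ``ValueError``.
    """
    variants = list(variants)
    _check_sorted(variants)
    accepted: list[StrainVariant] = []
    last_chrom, last_pos = None, None
    for v in variants:
        if v.chrom != last_chrom or v.pos - last_pos >= min_spacing_bp:
            accepted.append(v)
            last_chrom, last_pos = v.chrom, v.pos
    return accepted


def exclude_near_sites(candidates, reserved_sites, exclusion_window_bp: int) -> list[StrainVariant]:
    """Drop candidates within ``exclusion_window_bp`` (centre-to-centre,
    inclusive) of any reserved site on the same chromosome."""
    reserved_by_chrom: dict[str, np.ndarray] = {}
    for chrom in {r.chrom for r in reserved_sites}:
        reserved_by_chrom[chrom] = np.array(
            sorted(r.pos for r in reserved_sites if r.chrom == chrom)
        )
    kept = []
    for c in candidates:
        positions = reserved_by_chrom.get(c.chrom)
        if positions is None:
            kept.append(c)
            continue
        i = int(np.searchsorted(positions, c.pos))
        near = False
        for j in (i - 1, i):
            if 0 <= j < len(positions) and abs(c.pos - int(positions[j])) <= exclusion_window_bp:
                near = True
                break
        if not near:
            kept.append(c)
    return kept


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """Fetch reference sequence; accepts a mapping of chrom->sequence or an
    object with a pysam-style fetch(chrom, start, end)."""
    if hasattr(reference, "fetch"):
        return reference.fetch(chrom, start, end).upper()
    return reference[chrom][start:end].upper()


def _contig_length(reference, chrom: str) -> int:
    if hasattr(reference, "get_reference_length"):
        return reference.get_reference_length(chrom)
    return len(reference[chrom])


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C)."""
    gc = seq.count("G") + seq.count("C")
    return 2.0 * (len(seq) - gc) + 4.0 * gc


def max_homopolymer_run(seq: str) -> int:
    return max(len(m.group(0)) for m in re.finditer(r"(.)\1*", seq))


def _gc_window_score(frac: float, lo: float = 0.3, hi: float = 0.7) -> float:
    """1.0 inside [lo, hi], decaying linearly to 0 at the extremes."""
    if lo <= frac <= hi:
        return 1.0
    if frac < lo:
        return max(0.0, frac / lo)
    return max(0.0, (1.0 - frac) / (1.0 - hi))


def score_probe(ext_arm: str, lig_arm: str, snv_offset: int, gap_fill_len: int,
                weights: ScoringWeights | None = None) -> float:
    """Score a candidate probe; higher is better, -inf marks an unusable probe.

    Terms (each in [0, 1]):
      gc          — both arms near 30-70% GC
      tm          — arms melt together (Wallace-rule dTm, zero credit at >=10 C)
      homopolymer — no run longer than 4 nt in either arm
      centrality  — target SNV near the middle of the gap-fill
    """
    weights = weights or ScoringWeights()
    if not (_DNA_BASES.issuperset(ext_arm) and _DNA_BASES.issuperset(lig_arm)):
        return float("-inf")
    gc_term = 0.5 * (_gc_window_score(gc_fraction(ext_arm)) + _gc_window_score(gc_fraction(lig_arm)))
    tm_term = max(0.0, 1.0 - abs(wallace_tm(ext_arm) - wallace_tm(lig_arm)) / 10.0)
    homo_term = 1.0 if max(max_homopolymer_run(ext_arm), max_homopolymer_run(lig_arm)) <= 4 else 0.0
    half = (gap_fill_len - 1) / 2.0
    centrality = 1.0 - abs(snv_offset - half) / half if half > 0 else 1.0
    return (weights.gc * gc_term + weights.tm * tm_term
            + weights.homopolymer * homo_term + weights.centrality * centrality)


def design_probe(site: StrainVariant, reference, params: DesignParams | None = None) -> list[MipProbe]:
    """Emit scored probe candidates for one site, one per gap-fill placement.

    Candidates slide the gap-fill window so the SNV sits at different offsets
    (every ``snv_offset_step`` bases). Placements that would run off the
    contig are skipped with a warning; arms containing non-ACGT bases score
    -inf and are dropped.
    """
    params = params or DesignParams()
    pos0 = site.pos - 1  # 0-based
    clen = _contig_length(reference, site.chrom)
    candidates: list[MipProbe] = []
    offsets = list(range(0, params.gap_fill_len, params.snv_offset_step))
    for k, off in enumerate(offsets):
        gap_start = pos0 - off
        gap_end = gap_start + params.gap_fill_len
        ext_start = gap_start - params.ext_arm_len
        lig_end = gap_end + params.lig_arm_len
        if ext_start < 0 or lig_end > clen:
            logger.warning(
                "site %s:%d too close to contig edge for offset %d; candidate skipped",
                site.chrom, site.pos, off,
            )
            continue
        ext = _fetch(reference, site.chrom, ext_start, gap_start)
        gap = _fetch(reference, site.chrom, gap_start, gap_end)
        lig = _fetch(reference, site.chrom, gap_end, lig_end)
        score = score_probe(ext, lig, off, params.gap_fill_len, params.weights)
        if score == float("-inf"):
            continue
        candidates.append(MipProbe(
            probe_id=f"{site.strain_id}_{site.chrom}_{site.pos}_{k}",
            strain_id=site.strain_id,
            target=site,
            ext_arm_seq=ext,
            lig_arm_seq=lig,
            gap_fill_seq=gap,
            gap_fill_start=gap_start,
            snv_offset=off,
            score=score,
        ))
    return candidates


def _strain_rng(rng_seed: int, strain_id: str) -> np.random.Generator:
    """Per-strain substream: deterministic, independent of strain order."""
    return np.random.default_rng(
        np.random.SeedSequence([rng_seed, zlib.crc32(strain_id.encode())])
    )


def assign_panel(probes, params: DesignParams | None = None) -> dict[str, ProbePanel]:
    """Reduce scored candidates to one panel per strain.

    Per strain and chromosome the top scorer is kept (ties broken by the
    leftmost target position), then ``panel_size`` of the per-chromosome
    winners are sampled uniformly without replacement using a per-strain
    substream of ``rng_seed``. A strain covering fewer than ``panel_size``
    chromosomes is an error.
    """
    params = params or DesignParams()
    by_strain: dict[str, dict[str, MipProbe]] = {}
    for p in probes:
        best = by_strain.setdefault(p.strain_id, {})
        cur = best.get(p.target.chrom)
        if (cur is None or p.score > cur.score
                or (p.score == cur.score and p.target.pos < cur.target.pos)):
            best[p.target.chrom] = p
    panels: dict[str, ProbePanel] = {}
    for strain_id in sorted(by_strain):
        winners = [by_strain[strain_id][c]
                   for c in sorted(by_strain[strain_id], key=karyotype_key)]
        if len(winners) < params.panel_size:
            raise ValueError(
                f"strain {strain_id}: only {len(winners)} chromosomes covered, "
                f"need {params.panel_size}"
            )
        if len(winners) == params.panel_size:
            chosen = winners
        else:
            rng = _strain_rng(params.rng_seed, strain_id)
            idx = sorted(rng.choice(len(winners), size=params.panel_size, replace=False))
            chosen = [winners[i] for i in idx]
        panels[strain_id] = ProbePanel(strain_id=strain_id, probes=chosen)
    return panels


def design_panels(variants, reference, params: DesignParams | None = None,
                  reserved_sites=None) -> dict[str, ProbePanel]:
    """Full design pipeline: private sites -> spacing scan -> (optional
    exclusion against reserved sites) -> scored candidates -> panels."""
    params = params or DesignParams()
    private = remove_shared_variants(variants)
    sites = select_spaced_sites(sort_variants(private), params.min_spacing_bp)
    if reserved_sites:
        sites = exclude_near_sites(sites, reserved_sites, params.exclusion_window_bp)
    candidates: list[MipProbe] = []
    for site in sites:
        candidates.extend(design_probe(site, reference, params))
    return assign_panel(candidates, params)
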