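"""Generative model of pooled serial-transfer growth and MIP capture.

The growth model is a discrete-generation Wright-Fisher-with-selection
update: each transfer cycle, strain s with relative fitness w_s moves from
abundance A_s to expected abundance A_s*w_s / sum_j A_j*w_j, and the
realized next population is a multinomial draw of ``bottleneck_n``
individuals (the 5-10k animals transferred to a fresh plate). Setting
``bottleneck_n`` to None gives the deterministic infinite-population
update.

Sequencing is modeled at the capture-event level: each probe has a
persistent lognormal efficiency, its UMI total is Poisson around
``probe_depth_mean`` times that efficiency, and ALT events are binomial
with success probability A_s*(1-fpr) + (1-A_s)*fpr, where ``per_event_fpr``
is the per-event allele-miscall rate. The default lognormal sigma is
calibrated so the 1st-99th percentile of probe depth spans about ninefold.
FASTQ emission is exact: one read per capture event, so parsing the reads
back reproduces the generating count table identically.

All randomness flows from one seed; per-stage substreams are spawned
deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import quantify
from .fitness import ClassBounds, build_trajectories, fitness_pipeline
from .probe_design import MipProbe, ProbePanel, StrainVariant
from .quantify import COUNT_COLUMNS, ReadLayout

# ln(9) / (z_0.99 - z_0.01): lognormal sigma whose 1st-99th percentile
# ratio is ninefold.
NINEFOLD_SIGMA = math.log(9.0) / (2 * 2.3263478740408408)

DEPTH_MEAN_DEFAULT = 1566
FPR_DEFAULT = 1.3e-4


@dataclass
class SimStrain:
    """A pooled strain with per-generation relative fitness w."""

    strain_id: str
    fitness_w: float = 1.0
    initial_count: int = 20

    def __post_init__(self):
        if self.fitness_w <= 0:
            raise ValueError("fitness_w must be positive")
        if self.initial_count < 0:
            raise ValueError("initial_count must be >= 0")


@dataclass
class SimConfig:
    """Study conditions for one simulated pooling experiment."""

    strains: list[SimStrain]
    generations: int = 7
    bottleneck_n: int | None = 10_000
    probe_depth_mean: float = DEPTH_MEAN_DEFAULT
    probe_efficiency_sigma: float = NINEFOLD_SIGMA
    per_event_fpr: float = FPR_DEFAULT
    rng_seed: int = 0

    def __post_init__(self):
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.bottleneck_n is not None and self.bottleneck_n < 1:
            raise ValueError("bottleneck_n must be >= 1")


def _spawn(seed, *key_ints) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key_ints)]))


def simulate_growth(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate serial-transfer growth; returns a (generation x strain)
    abundance DataFrame whose rows each sum to 1.

    Generation 0 is the normalized initial counts. If every strain goes
    extinct the result is truncated at the last live generation and carries
    ``frame.attrs['extinct'] = True``.
    """
    rng = rng or _spawn(config.rng_seed, 1)
    ids = [s.strain_id for s in config.strains]
    w = np.array([s.fitness_w for s in config.strains], dtype=float)
    counts = np.array([s.initial_count for s in config.strains], dtype=float)
    if counts.sum() == 0:
        raise ValueError("initial population is empty")
    rows = [counts / counts.sum()]
    extinct = False
    for _ in range(config.generations):
        a = rows[-1]
        weighted = a * w
        total = weighted.sum()
        if total == 0:
            extinct = True
            break
        expected = weighted / total
        if config.bottleneck_n is None:
            rows.append(expected)
        else:
            draw = rng.multinomial(config.bottleneck_n, expected)
            rows.append(draw / config.bottleneck_n)
    frame = pd.DataFrame(rows, columns=ids)
    frame.index.name = "generation"
    frame.attrs["extinct"] = extinct
    return frame


def probe_efficiencies(panels: dict[str, ProbePanel], sigma: float,
                       rng: np.random.Generator) -> dict[str, float]:
    """Persistent per-probe capture efficiency, lognormal with median 1."""
    effs = {}
    for strain_id in sorted(panels):
        for probe in panels[strain_id].probes:
            effs[probe.probe_id] = float(rng.lognormal(mean=0.0, sigma=sigma))
    return effs


def simulate_counts(abundance: dict[str, float], panels: dict[str, ProbePanel],
                    config: SimConfig, library_id: str = "lib",
                    rng: np.random.Generator | None = None,
                    efficiencies: dict[str, float] | None = None) -> pd.DataFrame:
    """Capture-event count table for one library given true strain abundances.

    Per probe: total UMIs ~ Poisson(depth_mean x efficiency); ALT UMIs ~
    Binomial(total, A*(1-fpr) + (1-A)*fpr); REF is the remainder. Strains
    absent from ``abundance`` are simulated at abundance 0 (their ALT
    events are all false positives).
    """
    rng = rng or _spawn(config.rng_seed, 2)
    if efficiencies is None:
        eff_rng = _spawn(config.rng_seed, 3)
        efficiencies = probe_efficiencies(panels, config.probe_efficiency_sigma, eff_rng)
    fpr = config.per_event_fpr
    rows = []
    for strain_id in sorted(panels):
        a = float(abundance.get(strain_id, 0.0))
        for probe in panels[strain_id].probes:
            lam = config.probe_depth_mean * efficiencies[probe.probe_id]
            total = int(rng.poisson(lam))
            if total == 0:
                rows.append((library_id, probe.probe_id, 0, 0, 0, 0, 0))
                continue
            p_alt = a * (1.0 - fpr) + (1.0 - a) * fpr
            alt = int(rng.binomial(total, p_alt))
            rows.append((library_id, probe.probe_id, alt, total - alt, 0, total, 0))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


_BASE4 = "ACGT"


def _int_to_umi(i: int, umi_len: int) -> str:
    digits = []
    for _ in range(umi_len):
        digits.append(_BASE4[i % 4])
        i //= 4
    return "".join(reversed(digits))


_OTHER_BASE = {b: "ACGT"[("ACGT".index(b) + 1) % 4] for b in "ACGT"}


def simulate_reads(counts: pd.DataFrame, panels: dict[str, ProbePanel],
                   layout: ReadLayout | None = None) -> str:
    """Render a count table as FASTQ text, one read per capture event.

    Reads are [ext arm][gap-fill][lig arm] with the called allele at the
    probe's SNV offset; UMIs enumerate capture events (distinct within a
    probe), carried in the read header or inline per the layout. Parsing
    the output with :func:`mipfit.quantify.parse_reads` and deduplicating
    reproduces ``counts`` exactly.
    """
    layout = layout or ReadLayout()
    probes = {p.probe_id: p for panel in panels.values() for p in panel.probes}
    chunks = []
    for row in counts.itertuples():
        probe = probes[row.probe_id]
        if 4 ** layout.umi_len < row.total_umis:
            raise ValueError("umi_len too short for the event count")
        alleles = ([quantify.ALT] * row.alt_umis + [quantify.REF] * row.ref_umis
                   + [quantify.OTHER] * row.other_umis)
        for i, call in enumerate(alleles):
            umi = _int_to_umi(i, layout.umi_len)
            gap = list(probe.gap_fill_seq)
            if call == quantify.ALT:
                gap[probe.snv_offset] = probe.target.alt_allele
            elif call == quantify.OTHER:
                gap[probe.snv_offset] = _other_base(probe)
            seq = probe.ext_arm_seq + "".join(gap) + probe.lig_arm_seq
            name = f"{row.library_id}.{probe.probe_id}.{i}"
            if layout.umi_source == "inline":
                seq += umi
            else:
                name = f"{name}:{umi}"
            chunks.append(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
    return "".join(chunks)


def _other_base(probe: MipProbe) -> str:
    for b in "ACGT":
        if b not in (probe.target.ref_allele, probe.target.alt_allele):
            return b
    raise AssertionError("unreachable")


def toy_panels(n_strains: int = 3, panel_size: int = 4, gap_fill_len: int = 40,
               arm_len: int = 12, seed: int = 7) -> dict[str, ProbePanel]:
    """Small synthetic probe panels with random (but reproducible) arm and
    gap-fill sequences; no reference genome required. Used for simulation
    at the count level and for read round-trip exercises."""
    rng = _spawn(seed, 99)
    panels = {}
    chroms = ["I", "II", "III", "IV", "V", "X"]
    for s in range(n_strains):
        strain_id = f"S{s + 1:03d}"
        probes = []
        for k in range(panel_size):
            seqs = ["".join(rng.choice(list("ACGT"), size=n))
                    for n in (arm_len, gap_fill_len, arm_len)]
            ext, gap, lig = seqs
            off = gap_fill_len // 2
            ref = gap[off]
            alt = _OTHER_BASE[ref]
            pos = 1000 * (s * panel_size + k) + 500
            target = StrainVariant(strain_id, chroms[k % len(chroms)], pos, ref, alt)
            probes.append(MipProbe(
                probe_id=f"{strain_id}_p{k}", strain_id=strain_id, target=target,
                ext_arm_seq=ext, lig_arm_seq=lig, gap_fill_seq=gap,
                gap_fill_start=pos - 1 - off, snv_offset=off, score=1.0,
            ))
        panels[strain_id] = ProbePanel(strain_id=strain_id, probes=probes)
    return panels


def neutral_pool(n_strains: int = 50, focal: dict[str, float] | None = None,
                 initial_count: int = 20) -> list[SimStrain]:
    """A pool of neutral strains (w=1), optionally overriding focal strains
    with per-generation log2 fitness values relative to the neutral background."""
    strains = [SimStrain(f"S{i + 1:03d}", 1.0, initial_count) for i in range(n_strains)]
    if focal:
        by_id = {s.strain_id: s for s in strains}
        for strain_id, log2_w in focal.items():
            by_id[strain_id].fitness_w = 2.0 ** log2_w
    return strains


@dataclass
class RecoveryReport:
    """True-vs-estimated comparison from one simulated experiment."""

    per_strain: pd.DataFrame  # strain_id, true_log2_w, true class, est mean_fcr, est class
    bias: float
    rmse: float
    confusion: pd.DataFrame  # true class x estimated class counts


def recovery_experiment(config: SimConfig, n_replicates: int = 8,
                        panels: dict[str, ProbePanel] | None = None,
                        bounds: ClassBounds | None = None,
                        start_min: float = 2.5e-3, floor: float = 1e-3) -> RecoveryReport:
    """End-to-end check: simulate growth + capture, quantify, estimate
    fitness, and compare estimated FCR and class to the truth.

    Each replicate is an independent growth series sampled at every
    generation; counts flow through UMI-level quantification (count-level,
    no reads) into the fitness pipeline.
    """
    bounds = bounds or ClassBounds()
    panels = panels or toy_panels(n_strains=len(config.strains))
    probe_to_strain = {p.probe_id: s for s, panel in panels.items() for p in panel.probes}
    eff_rng = _spawn(config.rng_seed, 3)
    efficiencies = probe_efficiencies(panels, config.probe_efficiency_sigma, eff_rng)

    abundance_frames = []
    sheet_rows = []
    truth_frames = []
    for rep in range(n_replicates):
        growth_rng = _spawn(config.rng_seed, 10, rep)
        count_rng = _spawn(config.rng_seed, 20, rep)
        truth = simulate_growth(config, growth_rng)
        truth_frames.append(truth)
        for gen in truth.index:
            library_id = f"rep{rep}_g{gen}"
            counts = simulate_counts(truth.loc[gen].to_dict(), panels, config,
                                     library_id=library_id, rng=count_rng,
                                     efficiencies=efficiencies)
            retained, _ = quantify.library_qc(counts)
            abundance_frames.append(
                quantify.strain_abundance(counts, probe_to_strain, retained))
            sheet_rows.append((library_id, "pool1", f"rep{rep}", "sim", int(gen)))
    abundance = pd.concat(abundance_frames, ignore_index=True)
    sheet = pd.DataFrame(sheet_rows, columns=["library_id", "pool_id", "replicate_id",
                                              "condition", "generation"])
    trajectories = build_trajectories(abundance, sheet)
    _, summary = fitness_pipeline(trajectories, start_min=start_min, floor=floor,
                                  bounds=bounds)

    true_log2_w = {s.strain_id: math.log2(s.fitness_w) for s in config.strains}
    summary = summary.set_index("strain_id")
    rows = []
    for strain_id, tw in true_log2_w.items():
        true_cls = _true_class(tw, truth_frames, strain_id, bounds, start_min, floor)
        if strain_id in summary.index:
            est_fcr = float(summary.loc[strain_id, "mean_fcr"])
            est_cls = int(summary.loc[strain_id, "fitness_class"])
        else:
            est_fcr, est_cls = float("nan"), 0
        rows.append((strain_id, tw, true_cls, est_fcr, est_cls))
    per_strain = pd.DataFrame(rows, columns=["strain_id", "true_log2_w", "true_class",
                                             "est_mean_fcr", "est_class"])
    ok = per_strain["est_mean_fcr"].notna()
    err = per_strain.loc[ok, "est_mean_fcr"] - per_strain.loc[ok, "true_log2_w"]
    confusion = pd.crosstab(per_strain["true_class"], per_strain["est_class"])
    return RecoveryReport(
        per_strain=per_strain,
        bias=float(err.mean()) if ok.any() else float("nan"),
        rmse=float(np.sqrt((err ** 2).mean())) if ok.any() else float("nan"),
        confusion=confusion,
    )


def _true_class(true_log2_w: float, truth_frames, strain_id: str,
                bounds: ClassBounds, start_min: float, floor: float) -> int:
    """Class implied by the true fitness under the classification model,
    honouring the start filter on the true generation-0 abundances."""
    starts = [float(t.loc[0, strain_id]) for t in truth_frames]
    if float(np.mean(starts)) < start_min:
        return 0
    from .fitness import classify

    return classify(true_log2_w, bounds)
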