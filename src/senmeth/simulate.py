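"""Stochastic methylation-acquisition simulator.

Replicative senescence leaves continuous, site-specific DNA methylation
changes: at particular CpGs the methylation level drifts roughly linearly
with passage number, up (hypermethylation) or down (hypomethylation). The
generative model here treats each CpG's methylation probability at passage
``t`` as ``clip(p0 + slope * t, 0, 1)`` and draws diploid cells (two
independent epialleles per CpG). Clonal bottlenecks — the limiting-dilution
subcloning used to isolate single-cell-derived colonies — are modeled by
copying one founder cell's epialleles into every cell of the subclone, with
an optional per-allele switch rate after the bottleneck.

From a population the simulator emits:

* bisulfite amplicon reads (FASTQ) with configurable bisulfite-conversion
  failure, inappropriate conversion of methylated cytosines, and sequencing
  error — the substrate for demultiplexing, methylation calling and
  read-level co-methylation analysis;
* array-like beta matrices with planted senescence-drifting CpGs whose
  annotation mimics the observed depletion of drift from promoters and CpG
  islands — the substrate for differential-methylation analysis.

All randomness flows through a single :class:`numpy.random.Generator`; a
fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .amplicon_io import (
    BARCODE_HEADER_TAG,
    BARCODE_LENGTH,
    AmpliconSpec,
    FastqRead,
    SampleSheet,
    write_fastq,
    write_panel,
)

__all__ = [
    "CpGDriftParams",
    "SimulationConfig",
    "CloneEpigenotype",
    "CellPopulation",
    "SimulatedRead",
    "AnnotationScheme",
    "expected_methylation",
    "sample_bulk",
    "sample_clone",
    "generate_reads",
    "generate_beta_matrix",
    "default_panel",
    "default_drift",
    "default_config",
    "make_barcodes",
    "simulate_bbaseq_run",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CpGDriftParams:
    """Linear passage drift of one CpG's methylation probability.

    ``p0`` is the methylation probability at passage 0 and ``slope`` the
    change per passage (negative for senescence-associated hypomethylation).
    """

    cpg_id: str
    p0: float
    slope: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError(f"{self.cpg_id}: p0 must be in [0, 1], got {self.p0}")


def expected_methylation(params: CpGDriftParams, passage: float) -> float:
    """Expected methylation probability at a passage: ``clip(p0 + slope*t, 0, 1)``."""
    if passage < 0:
        raise ValueError("passage must be non-negative")
    return float(np.clip(params.p0 + params.slope * passage, 0.0, 1.0))


@dataclass
class SimulationConfig:
    """Full parameterisation of a simulated BBA-Seq experiment.

    ``drift`` maps amplicon name to one :class:`CpGDriftParams` per CpG of
    that amplicon (same order as ``AmpliconSpec.cpg_offsets``).
    ``anchor_correlation`` optionally couples each neighbor CpG to the
    amplicon's signature (anchor) CpG: with probability rho the neighbor
    allele copies the anchor allele's state, otherwise it draws
    independently — the mechanism behind bulk co-methylation decay profiles.
    """

    amplicons: list[AmpliconSpec]
    drift: dict[str, list[CpGDriftParams]]
    n_cells_bulk: int = 2000
    passages: list[int] = field(default_factory=lambda: list(range(2, 21, 2)))
    cpd_per_passage: float = 2.5
    conversion_failure_rate: float = 0.005
    inappropriate_conversion_rate: float = 0.002
    seq_error_rate: float = 0.001
    reads_per_sample: int = 2000
    seed: int = 0
    anchor_correlation: float = 0.0
    barcode_location: str = "header"

    def __post_init__(self) -> None:
        for name, rate in (
            ("conversion_failure_rate", self.conversion_failure_rate),
            ("inappropriate_conversion_rate", self.inappropriate_conversion_rate),
            ("seq_error_rate", self.seq_error_rate),
            ("anchor_correlation", self.anchor_correlation),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if self.n_cells_bulk <= 0:
            raise ValueError("n_cells_bulk must be positive")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        for spec in self.amplicons:
            params = self.drift.get(spec.name)
            if params is None:
                raise ValueError(f"no drift parameters for amplicon {spec.name}")
            if len(params) != spec.n_cpgs:
                raise ValueError(
                    f"amplicon {spec.name}: {spec.n_cpgs} CpGs but "
                    f"{len(params)} drift parameter sets"
                )

    def amplicon(self, name: str) -> AmpliconSpec:
        for spec in self.amplicons:
            if spec.name == name:
                return spec
        raise KeyError(f"amplicon {name!r} not in panel")

    def cpd(self, passage: float) -> float:
        return self.cpd_per_passage * passage

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["amplicons"] = [dataclasses.asdict(a) for a in self.amplicons]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        d["amplicons"] = [AmpliconSpec(**a) for a in d["amplicons"]]
        d["drift"] = {
            name: [CpGDriftParams(**p) for p in params]
            for name, params in d["drift"].items()
        }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class CloneEpigenotype:
    """The diploid epiallele states of one founder cell.

    ``alleles`` maps amplicon name to a boolean array of shape
    ``(2, n_cpgs)`` (True = methylated).
    """

    alleles: dict[str, np.ndarray]
    founder_passage: float

    def __post_init__(self) -> None:
        for name, arr in self.alleles.items():
            if arr.shape[0] != 2:
                raise ValueError(f"{name}: founder must carry exactly 2 alleles per CpG")


@dataclass
class CellPopulation:
    """A set of simulated diploid cells.

    ``alleles`` maps amplicon name to a boolean array of shape
    ``(n_cells, 2, n_cpgs)``. ``provenance`` is ``"bulk"`` or ``"clone"``.
    """

    alleles: dict[str, np.ndarray]
    passage: float
    provenance: str = "bulk"
    founder: CloneEpigenotype | None = None

    def __post_init__(self) -> None:
        if self.n_cells == 0:
            raise ValueError("population must contain at least one cell")

    @property
    def n_cells(self) -> int:
        return next(iter(self.alleles.values())).shape[0]

    def beta(self, amplicon: str | None = None) -> np.ndarray | dict[str, np.ndarray]:
        """Per-CpG methylation level: methylated alleles / (2 * n_cells), exact."""
        if amplicon is not None:
            return self.alleles[amplicon].mean(axis=(0, 1))
        return {name: arr.mean(axis=(0, 1)) for name, arr in self.alleles.items()}


def _passage_probabilities(
    config: SimulationConfig, amplicon: AmpliconSpec, passage: float
) -> np.ndarray:
    return np.array(
        [expected_methylation(p, passage) for p in config.drift[amplicon.name]]
    )


def sample_bulk(
    config: SimulationConfig, passage: float, rng: np.random.Generator
) -> CellPopulation:
    """Draw a bulk population: each allele an independent Bernoulli draw.

    Allele states at each CpG are independent across cells and alleles with
    success probability ``expected_methylation``; if
    ``config.anchor_correlation`` is nonzero, each non-anchor CpG copies the
    anchor allele's state with that probability instead of drawing
    independently (marginal probabilities are preserved only approximately
    when anchor and neighbor probabilities differ; the coupling is intended
    for co-methylation demonstrations, default 0).
    """
    alleles: dict[str, np.ndarray] = {}
    n = config.n_cells_bulk
    rho = config.anchor_correlation
    for spec in config.amplicons:
        p = _passage_probabilities(config, spec, passage)
        draws = rng.random((n, 2, spec.n_cpgs)) < p
        if rho > 0 and spec.n_cpgs > 1:
            anchor = draws[:, :, spec.signature_index]
            copy = rng.random((n, 2, spec.n_cpgs)) < rho
            copy[:, :, spec.signature_index] = False
            draws = np.where(copy, anchor[:, :, None], draws)
        alleles[spec.name] = draws
    return CellPopulation(alleles=alleles, passage=passage, provenance="bulk")


def sample_clone(
    population: CellPopulation,
    n_cells_out: int,
    post_switch_rate: float,
    rng: np.random.Generator,
) -> CellPopulation:
    """Clonal bottleneck: pick one founder, expand it into a subclone.

    A founder cell is chosen uniformly from ``population``; every output
    cell copies the founder's diploid epialleles and then flips each allele
    state independently with probability ``post_switch_rate`` (0 gives a
    perfectly clonal population whose per-CpG beta is 0, 0.5 or 1).
    """
    if n_cells_out <= 0:
        raise ValueError("n_cells_out must be positive")
    if not 0.0 <= post_switch_rate <= 1.0:
        raise ValueError("post_switch_rate must be in [0, 1]")
    idx = int(rng.integers(population.n_cells))
    founder = CloneEpigenotype(
        alleles={name: arr[idx].copy() for name, arr in population.alleles.items()},
        founder_passage=population.passage,
    )
    alleles = {}
    for name, fa in founder.alleles.items():
        tiled = np.broadcast_to(fa, (n_cells_out, *fa.shape)).copy()
        if post_switch_rate > 0:
            flips = rng.random(tiled.shape) < post_switch_rate
            tiled ^= flips
        alleles[name] = tiled
    return CellPopulation(
        alleles=alleles, passage=population.passage, provenance="clone", founder=founder
    )


# ---------------------------------------------------------------------------
# read generation


@dataclass
class SimulatedRead:
    """One simulated amplicon read plus its generative ground truth."""

    name: str
    sequence: str
    amplicon: str
    cell_index: int
    allele_index: int
    true_states: np.ndarray  # boolean per CpG, the sampled allele's truth


def generate_reads(
    population: CellPopulation,
    amplicon: AmpliconSpec,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_reads: int | None = None,
    coverage_mode: str = "multinomial",
    read_prefix: str = "read",
) -> list[SimulatedRead]:
    """Emit bisulfite reads for one amplicon from a population.

    Each read is drawn from one random allele of one random cell
    (``coverage_mode="multinomial"``) or by cycling deterministically through
    every (cell, allele) pair (``"stratified"``, which makes the read pool's
    allele fractions match the population exactly). Base conversion follows
    bisulfite chemistry on the top strand: methylated CpG cytosines read
    ``C`` (except with ``inappropriate_conversion_rate``), unmethylated CpG
    cytosines and all non-CpG cytosines read ``T`` (except with
    ``conversion_failure_rate``); uniform substitution errors are applied
    last at ``seq_error_rate`` per base.
    """
    if amplicon.name not in population.alleles:
        raise KeyError(f"amplicon {amplicon.name!r} not simulated in this population")
    if coverage_mode not in ("multinomial", "stratified"):
        raise ValueError(f"unknown coverage_mode {coverage_mode!r}")
    n_reads = config.reads_per_sample if n_reads is None else n_reads
    alleles = population.alleles[amplicon.name]
    n_cells = alleles.shape[0]

    if coverage_mode == "multinomial":
        cell_idx = rng.integers(n_cells, size=n_reads)
        allele_idx = rng.integers(2, size=n_reads)
    else:
        pairs = n_cells * 2
        order = np.tile(np.arange(pairs), -(-n_reads // pairs))[:n_reads]
        cell_idx, allele_idx = order // 2, order % 2
    states = alleles[cell_idx, allele_idx, :]  # (n_reads, n_cpgs)

    ref = np.frombuffer(amplicon.ref_seq.encode("ascii"), dtype=np.uint8)
    reads = np.broadcast_to(ref, (n_reads, len(ref))).copy()
    C, T = ord("C"), ord("T")

    cpg = np.array(amplicon.cpg_offsets, dtype=int)
    if len(cpg):
        meth = states
        # methylated C stays C unless inappropriately converted
        inapp = rng.random(meth.shape) < config.inappropriate_conversion_rate
        # unmethylated C converts to T unless conversion fails
        fail = rng.random(meth.shape) < config.conversion_failure_rate
        cpg_base = np.where(meth, np.where(inapp, T, C), np.where(fail, C, T))
        reads[:, cpg] = cpg_base
    non_cpg_c = np.array(amplicon.non_cpg_c_offsets, dtype=int)
    if len(non_cpg_c):
        fail = rng.random((n_reads, len(non_cpg_c))) < config.conversion_failure_rate
        reads[:, non_cpg_c] = np.where(fail, C, T)
    if config.seq_error_rate > 0:
        err = rng.random(reads.shape) < config.seq_error_rate
        # substitute with one of the three other bases, uniformly
        shift = rng.integers(1, 4, size=reads.shape)
        base_idx = np.searchsorted(_BASES, reads)
        reads = np.where(err, _BASES[(base_idx + shift) % 4], reads)

    out = []
    for i in range(n_reads):
        out.append(
            SimulatedRead(
                name=f"{read_prefix}_{amplicon.name}_{i}",
                sequence=reads[i].tobytes().decode("ascii"),
                amplicon=amplicon.name,
                cell_index=int(cell_idx[i]),
                allele_index=int(allele_idx[i]),
                true_states=states[i].copy(),
            )
        )
    return out


def make_barcodes(n: int, rng: np.random.Generator, min_distance: int = 5) -> list[str]:
    """Generate ``n`` 12-bp barcodes pairwise at least ``min_distance`` apart."""
    bases = "ACGT"
    out: list[str] = []
    while len(out) < n:
        cand = "".join(bases[i] for i in rng.integers(4, size=BARCODE_LENGTH))
        if all(sum(a != b for a, b in zip(cand, prev)) >= min_distance for prev in out):
            out.append(cand)
    return out


def reads_to_fastq(
    sim_reads: Iterable[SimulatedRead],
    barcode: str,
    barcode_location: str = "header",
) -> list[FastqRead]:
    """Attach the sample barcode (header ``BC:`` tag or inline 12-bp prefix)."""
    records = []
    for r in sim_reads:
        if barcode_location == "header":
            records.append(FastqRead(f"{r.name} {BARCODE_HEADER_TAG}{barcode}", r.sequence))
        elif barcode_location == "inline":
            records.append(FastqRead(r.name, barcode + r.sequence))
        else:
            raise ValueError(f"unknown barcode_location {barcode_location!r}")
    return records


def simulate_bbaseq_run(
    config: SimulationConfig,
    out_dir: str | Path,
    clones_per_passage: int = 0,
    clone_cells: int = 200,
    post_switch_rate: float = 0.0,
) -> dict:
    """Simulate a full multiplexed BBA-Seq experiment and write its files.

    One bulk sample per passage in ``config.passages`` (plus optional
    zero-switch subclones of each bulk), all pooled into a single FASTQ with
    per-sample barcodes. Writes: panel FASTA + CpG BED, sample sheet TSV,
    pooled FASTQ, and a ground-truth JSON (drift parameters, per-sample true
    betas, founder epigenotypes). Returns a manifest of paths plus the
    per-sample populations.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    samples: list[dict] = []
    populations: dict[str, CellPopulation] = {}
    for passage in config.passages:
        bulk = sample_bulk(config, passage, rng)
        sid = f"bulk_p{passage:02d}"
        populations[sid] = bulk
        samples.append({"sample_id": sid, "passage": passage, "cpd": config.cpd(passage)})
        for c in range(clones_per_passage):
            clone = sample_clone(bulk, clone_cells, post_switch_rate, rng)
            cid = f"clone_p{passage:02d}_{c:02d}"
            populations[cid] = clone
            samples.append(
                {"sample_id": cid, "passage": passage, "cpd": config.cpd(passage)}
            )

    barcodes = make_barcodes(len(samples), rng)
    for row, bc in zip(samples, barcodes):
        row["barcode"] = bc
    sheet = SampleSheet(pd.DataFrame(samples)[["sample_id", "barcode", "passage", "cpd"]])

    all_records: list[FastqRead] = []
    truth: dict = {
        "seed": config.seed,
        "drift": {
            name: [dataclasses.asdict(p) for p in params]
            for name, params in config.drift.items()
        },
        "samples": {},
    }
    for row in samples:
        sid = row["sample_id"]
        pop = populations[sid]
        sample_truth = {"passage": row["passage"], "provenance": pop.provenance, "beta": {}}
        if pop.founder is not None:
            sample_truth["founder"] = {
                name: arr.astype(int).tolist() for name, arr in pop.founder.alleles.items()
            }
        for spec in config.amplicons:
            sim_reads = generate_reads(
                pop, spec, config, rng, read_prefix=sid,
                n_reads=max(1, config.reads_per_sample // len(config.amplicons)),
            )
            all_records.extend(
                reads_to_fastq(sim_reads, row["barcode"], config.barcode_location)
            )
            sample_truth["beta"][spec.name] = pop.beta(spec.name).tolist()
        truth["samples"][sid] = sample_truth

    paths = {
        "fastq": out_dir / "reads.fastq",
        "panel_fasta": out_dir / "panel.fasta",
        "panel_bed": out_dir / "panel_cpgs.bed",
        "sample_sheet": out_dir / "samples.tsv",
        "ground_truth": out_dir / "ground_truth.json",
    }
    write_fastq(all_records, paths["fastq"])
    write_panel(config.amplicons, paths["panel_fasta"], paths["panel_bed"])
    sheet.to_tsv(paths["sample_sheet"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "sheet": sheet,
        "populations": populations,
    }


# ---------------------------------------------------------------------------
# array-like beta matrices


@dataclass
class AnnotationScheme:
    """Category frequencies for array-style CpG annotation.

    ``refgene_probs`` / ``cgi_probs`` give the background composition of the
    simulated array; ``depleted_categories`` lists the classes from which
    senescence-drifting CpGs are under-drawn by ``depletion_factor``
    (drift concentrates away from promoters and CpG islands).
    """

    refgene_probs: dict[str, float] = field(
        default_factory=lambda: {
            "TSS1500": 0.13, "TSS200": 0.10, "5'UTR": 0.12, "1stExon": 0.06,
            "Body": 0.31, "3'UTR": 0.04, "Intergenic": 0.24,
        }
    )
    cgi_probs: dict[str, float] = field(
        default_factory=lambda: {
            "Island": 0.31, "Shore": 0.23, "Shelf": 0.10, "OpenSea": 0.36,
        }
    )
    depleted_categories: tuple[str, ...] = (
        "TSS1500", "TSS200", "5'UTR", "1stExon", "Island", "Shore",
    )
    depletion_factor: float = 0.15


def generate_beta_matrix(
    n_cpgs: int,
    n_samples_per_group: int,
    fraction_drifting: float,
    rng: np.random.Generator,
    effect_size: float = 0.3,
    noise_sd: float = 0.02,
    annotation_scheme: AnnotationScheme | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate an array-style beta matrix with planted senescence drift.

    Returns ``(betas, groups_annotation, truth)``:

    * ``betas`` — DataFrame CpG × sample, values in [0, 1]; sample names
      ``early_*`` / ``late_*``.
    * ``annotation`` — per CpG: ``refgene_group``, ``cgi_relation``.
    * ``truth`` — per CpG: ``is_drifting`` and ``direction`` (+1 hyper, -1
      hypo, 0 stable).

    Drifting CpGs shift their mean beta by ±``effect_size`` between the
    early and late group; they are preferentially drawn from categories
    outside promoters/CGIs per ``annotation_scheme``. Gaussian measurement
    noise ``noise_sd`` is added per observation and betas are truncated to
    [0, 1].
    """
    if not 0.0 <= effect_size <= 1.0:
        raise ValueError("effect_size must be in [0, 1]")
    if not 0.0 <= fraction_drifting <= 1.0:
        raise ValueError("fraction_drifting must be in [0, 1]")
    scheme = annotation_scheme or AnnotationScheme()
    ids = np.array([f"cg{i:08d}" for i in range(n_cpgs)])

    def _draw(probs: dict[str, float]) -> np.ndarray:
        cats = list(probs)
        p = np.array([probs[c] for c in cats], dtype=float)
        return np.array(cats)[rng.choice(len(cats), size=n_cpgs, p=p / p.sum())]

    refgene = _draw(scheme.refgene_probs)
    cgi = _draw(scheme.cgi_probs)

    n_drift = int(round(fraction_drifting * n_cpgs))
    weights = np.ones(n_cpgs)
    depleted = set(scheme.depleted_categories)
    weights[np.isin(refgene, list(depleted))] *= scheme.depletion_factor
    weights[np.isin(cgi, list(depleted))] *= scheme.depletion_factor
    drifting = np.zeros(n_cpgs, dtype=bool)
    if n_drift:
        chosen = rng.choice(n_cpgs, size=n_drift, replace=False, p=weights / weights.sum())
        drifting[chosen] = True

    # baseline levels: leave headroom for the planted shift
    base = rng.uniform(0.05, 0.95, size=n_cpgs)
    direction = np.zeros(n_cpgs, dtype=int)
    hyper = drifting & (rng.random(n_cpgs) < 0.5)
    hypo = drifting & ~hyper
    direction[hyper], direction[hypo] = 1, -1
    base[hyper] = rng.uniform(0.05, 1.0 - effect_size - 0.05, size=hyper.sum())
    base[hypo] = rng.uniform(effect_size + 0.05, 0.95, size=hypo.sum())

    cols, data = [], []
    for group, shift in (("early", 0.0), ("late", effect_size)):
        for s in range(n_samples_per_group):
            mean = base + direction * shift
            data.append(np.clip(mean + rng.normal(0, noise_sd, size=n_cpgs), 0, 1))
            cols.append(f"{group}_{s}")
    betas = pd.DataFrame(np.column_stack(data), index=ids, columns=cols)
    annotation = pd.DataFrame(
        {"refgene_group": refgene, "cgi_relation": cgi}, index=ids
    )
    truth = pd.DataFrame({"is_drifting": drifting, "direction": direction}, index=ids)
    return betas, annotation, truth


# ---------------------------------------------------------------------------
# default synthetic panel


def _fill_sequence(
    length: int, cpg_offsets: Sequence[int], rng: np.random.Generator
) -> str:
    """Random sequence with CG dinucleotides exactly at the given offsets.

    Ensures no accidental CG elsewhere so that every tracked CpG is a real
    CpG and all remaining cytosines are bona fide non-CpG conversion-QC
    sites.
    """
    seq = [""] * length
    for o in cpg_offsets:
        seq[o], seq[o + 1] = "C", "G"
    bases = "ACGT"
    for i in range(length):
        if seq[i]:
            continue
        while True:
            b = bases[int(rng.integers(4))]
            prev = seq[i - 1] if i > 0 else ""
            nxt = seq[i + 1] if i + 1 < length else ""
            if prev == "C" and b == "G":
                continue
            if b == "C" and nxt == "G":
                continue
            seq[i] = b
            break
    return "".join(seq)


#: synthetic/illustrative layout: (gene, length, cpg_offsets, signature_index)
_DEFAULT_LAYOUT = [
    ("GRM7", 140, (8, 30, 55, 82, 110), 0),
    ("CASR", 160, (6, 20, 33, 57, 84, 112, 141), 0),  # 7 CpGs, anchor first
    ("SELP", 130, (12, 40, 66, 95), 1),
    ("CASP14", 150, (10, 35, 72, 104, 128), 2),
    ("KRTAP13-3", 120, (14, 44, 78, 102), 0),
    ("PRAMEF2", 135, (9, 28, 61, 92, 118), 1),
]

#: per-gene signature-CpG drift (p0, slope per passage); neighbors get
#: milder drift. Chosen to emulate high-dynamic-range senescence CpGs that
#: traverse most of the beta scale across passages 2-20.
_SIGNATURE_DRIFT = {
    "GRM7": (0.03, 0.047),
    "CASR": (0.04, 0.046),
    "SELP": (0.05, 0.045),
    "CASP14": (0.97, -0.047),
    "KRTAP13-3": (0.96, -0.046),
    "PRAMEF2": (0.03, 0.047),
}


def default_panel(seed: int = 20160) -> list[AmpliconSpec]:
    """The packaged synthetic/illustrative six-gene amplicon panel.

    Sequences are generated, not genomic: real primer coordinates for the
    senescence-signature assays are not distributed with this package. The
    CASR amplicon carries seven CpGs with the signature CpG first, the
    layout used for neighboring-CpG and anchored co-methylation analyses.
    """
    rng = np.random.default_rng(seed)
    panel = []
    for gene, length, offsets, sig in _DEFAULT_LAYOUT:
        seq = _fill_sequence(length, offsets, rng)
        panel.append(
            AmpliconSpec(
                name=gene, gene=gene, ref_seq=seq, cpg_offsets=offsets,
                signature_index=sig,
            )
        )
    return panel


def default_drift(
    panel: Sequence[AmpliconSpec] | None = None, seed: int = 20161
) -> dict[str, list[CpGDriftParams]]:
    """Drift parameters for :func:`default_panel`.

    Signature CpGs drift strongly and linearly (|slope| about 0.04-0.045
    per passage across nearly the full beta range); neighboring CpGs drift
    in the same direction but more mildly, with varied baselines.
    """
    panel = panel if panel is not None else default_panel()
    rng = np.random.default_rng(seed)
    drift: dict[str, list[CpGDriftParams]] = {}
    for spec in panel:
        p0_sig, slope_sig = _SIGNATURE_DRIFT[spec.gene]
        params = []
        for i in range(spec.n_cpgs):
            if i == spec.signature_index:
                p0, slope = p0_sig, slope_sig
            else:
                slope = np.sign(slope_sig) * rng.uniform(0.008, 0.022)
                p0 = (
                    rng.uniform(0.10, 0.45)
                    if slope > 0
                    else rng.uniform(0.55, 0.90)
                )
            params.append(
                CpGDriftParams(cpg_id=f"{spec.name}_cpg{i}", p0=round(float(p0), 4),
                               slope=round(float(slope), 4))
            )
        drift[spec.name] = params
    return drift


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A ready-to-run :class:`SimulationConfig` on the packaged panel."""
    panel = default_panel()
    return SimulationConfig(
        amplicons=panel, drift=default_drift(panel), seed=seed, **overrides
    )
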