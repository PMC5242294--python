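"""Amplicon panel handling, barcode demultiplexing and read-to-amplicon assignment.

Targeted bisulfite amplicon sequencing (BBA-Seq) produces primer-anchored
reads from a small panel of PCR amplicons, multiplexed with 12-bp sample
barcodes. This module reads the panel definition (FASTA reference plus a BED
file of CpG positions), splits a FASTQ by barcode, and assigns each read to
its amplicon by ungapped, bisulfite-aware comparison against the reference
(a reference ``C`` matches a read ``C`` or ``T``, since unmethylated
cytosines read as ``T`` after conversion).
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

BARCODE_LENGTH = 12
#: token prefix used when the sample barcode travels in the FASTQ header
BARCODE_HEADER_TAG = "BC:"

__all__ = [
    "AmpliconSpec",
    "SampleSheet",
    "FastqRead",
    "AssignmentResult",
    "read_panel",
    "write_panel",
    "read_fastq",
    "write_fastq",
    "demultiplex",
    "assign_to_amplicon",
    "assignment_stats",
]


class FastqRead(NamedTuple):
    """One sequencing read (name includes any header comment)."""

    name: str
    sequence: str
    quality: str = ""


@dataclass(frozen=True)
class AmpliconSpec:
    """One targeted region: reference sequence plus its CpG coordinates.

    Parameters
    ----------
    name : unique amplicon identifier.
    gene : associated gene symbol (e.g. one of the six senescence-signature
        genes GRM7, CASR, SELP, CASP14, KRTAP13-3, PRAMEF2).
    ref_seq : unconverted genomic top-strand sequence of the amplified region.
    cpg_offsets : 0-based offsets of the CpG cytosines, strictly ascending.
    signature_index : index into ``cpg_offsets`` of the clock CpG.
    """

    name: str
    gene: str
    ref_seq: str
    cpg_offsets: tuple[int, ...]
    signature_index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref_seq", self.ref_seq.upper())
        object.__setattr__(self, "cpg_offsets", tuple(self.cpg_offsets))
        offs = self.cpg_offsets
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError(f"amplicon {self.name}: CpG offsets not strictly increasing")
        for o in offs:
            if o < 0 or o + 1 >= len(self.ref_seq):
                raise ValueError(f"amplicon {self.name}: CpG offset {o} outside reference")
            if self.ref_seq[o] != "C" or self.ref_seq[o + 1] != "G":
                raise ValueError(
                    f"amplicon {self.name}: offset {o} is not a CpG "
                    f"(found {self.ref_seq[o:o + 2]!r})"
                )
        if offs and not (0 <= self.signature_index < len(offs)):
            raise ValueError(f"amplicon {self.name}: signature_index out of range")
        if not offs:
            logger.warning("amplicon %s has no CpG sites", self.name)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_offsets)

    @property
    def signature_offset(self) -> int:
        return self.cpg_offsets[self.signature_index]

    @property
    def non_cpg_c_offsets(self) -> tuple[int, ...]:
        """Offsets of cytosines outside tracked CpGs (bisulfite-conversion QC sites)."""
        cpg = set(self.cpg_offsets)
        return tuple(i for i, b in enumerate(self.ref_seq) if b == "C" and i not in cpg)


@dataclass
class SampleSheet:
    """Sample-to-barcode mapping with optional passage / cPD metadata.

    ``table`` columns: sample_id, barcode, passage, cpd (passage and cpd may
    be missing). Barcodes must be unique 12-mers.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "barcode"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        for col in ("passage", "cpd"):
            if col not in self.table.columns:
                self.table[col] = np.nan
        barcodes = self.table["barcode"].astype(str)
        if barcodes.duplicated().any():
            raise ValueError("sample sheet barcodes are not unique")
        bad = barcodes[barcodes.str.len() != BARCODE_LENGTH]
        if len(bad):
            raise ValueError(f"barcodes must be {BARCODE_LENGTH} bp, got {bad.iloc[0]!r}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"barcode": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @property
    def barcodes(self) -> dict[str, str]:
        return dict(zip(self.table["barcode"], self.table["sample_id"]))

    def metadata(self, sample_id: str) -> pd.Series:
        return self.table.set_index("sample_id").loc[sample_id]


# ---------------------------------------------------------------------------
# panel I/O


def read_panel(fasta_path: str | Path, cpg_bed_path: str | Path) -> list[AmpliconSpec]:
    """Load amplicon specs from a FASTA reference and a CpG BED file.

    The BED file is 0-based half-open; each interval marks one CpG cytosine.
    A 4th (name) column equal to ``signature`` marks the clock CpG of that
    amplicon. The FASTA description may carry ``gene=SYMBOL``.
    """
    records = {rec.id: rec for rec in SeqIO.parse(str(fasta_path), "fasta")}
    bed = pd.read_csv(
        cpg_bed_path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name"],
        usecols=[0, 1, 2, 3],
        dtype={"chrom": str, "name": str},
    )
    unknown = set(bed["chrom"]) - set(records)
    if unknown:
        raise ValueError(f"BED references unknown amplicons: {sorted(unknown)}")
    specs = []
    for name, rec in records.items():
        sub = bed[bed["chrom"] == name].sort_values("start")
        offsets = tuple(int(s) for s in sub["start"])
        sig_rows = np.flatnonzero(sub["name"].values == "signature")
        signature_index = int(sig_rows[0]) if len(sig_rows) else 0
        gene = name
        for token in rec.description.split():
            if token.startswith("gene="):
                gene = token[5:]
        specs.append(
            AmpliconSpec(
                name=name,
                gene=gene,
                ref_seq=str(rec.seq),
                cpg_offsets=offsets,
                signature_index=signature_index if offsets else 0,
            )
        )
    return sorted(specs, key=lambda s: s.name)


def write_panel(
    panel: Sequence[AmpliconSpec], fasta_path: str | Path, cpg_bed_path: str | Path
) -> None:
    """Write the panel reference FASTA and CpG BED (inverse of :func:`read_panel`)."""
    with open(fasta_path, "w") as fa:
        for spec in panel:
            fa.write(f">{spec.name} gene={spec.gene}\n{spec.ref_seq}\n")
    with open(cpg_bed_path, "w") as bed:
        for spec in panel:
            for i, o in enumerate(spec.cpg_offsets):
                label = "signature" if i == spec.signature_index else "cpg"
                bed.write(f"{spec.name}\t{o}\t{o + 1}\t{label}\n")


# ---------------------------------------------------------------------------
# FASTQ I/O


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Iterate reads from a (optionally gzipped) FASTQ file."""
    with _open_text(path) as handle:
        for title, seq, qual in _fastq_iterator(handle):
            yield FastqRead(title, seq, qual)


def _fastq_iterator(handle):
    # Bio.SeqIO.QualityIO.FastqGeneralIterator: fast (title, seq, qual) tuples
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    return FastqGeneralIterator(handle)


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as out:
        for read in reads:
            qual = read.quality or "I" * len(read.sequence)
            out.write(f"@{read.name}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# demultiplexing


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _barcode_from_header(name: str) -> str | None:
    for token in name.split():
        if token.startswith(BARCODE_HEADER_TAG):
            return token[len(BARCODE_HEADER_TAG):]
    return None


def demultiplex(
    reads: Iterable[FastqRead] | str | Path,
    sample_sheet: SampleSheet,
    max_barcode_mismatch: int = 1,
    barcode_location: str = "header",
) -> dict[str, list[FastqRead]]:
    """Split reads by sample barcode.

    Each read is assigned to the unique barcode within ``max_barcode_mismatch``
    Hamming distance; reads matching no barcode, or equidistant to two, go to
    the ``"undetermined"`` bin. With ``barcode_location="inline"`` the first
    12 bases of the read are the barcode and are trimmed on assignment; with
    ``"header"`` the barcode travels as a ``BC:`` token in the header comment.

    Raises
    ------
    ValueError
        If two sheet barcodes lie within ``2 * max_barcode_mismatch`` of each
        other (assignment would be ambiguous by construction).
    """
    if barcode_location not in ("header", "inline"):
        raise ValueError(f"unknown barcode_location {barcode_location!r}")
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)

    barcode_map = sample_sheet.barcodes
    barcodes = list(barcode_map)
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1:]:
            if _hamming(a, b) <= 2 * max_barcode_mismatch:
                raise ValueError(
                    f"barcodes {a} and {b} are within {2 * max_barcode_mismatch} "
                    "mismatches of each other: ambiguous at this tolerance"
                )

    bins: dict[str, list[FastqRead]] = {s: [] for s in barcode_map.values()}
    bins["undetermined"] = []
    for read in reads:
        if barcode_location == "header":
            observed = _barcode_from_header(read.name)
            trimmed = read
        else:
            observed = read.sequence[:BARCODE_LENGTH]
            trimmed = FastqRead(
                read.name, read.sequence[BARCODE_LENGTH:], read.quality[BARCODE_LENGTH:]
            )
        if not observed or len(observed) != BARCODE_LENGTH:
            bins["undetermined"].append(read)
            continue
        dists = [(_hamming(observed, bc), bc) for bc in barcodes]
        dists.sort(key=lambda t: t[0])
        best, best_bc = dists[0]
        runner_up = dists[1][0] if len(dists) > 1 else None
        if best <= max_barcode_mismatch and (runner_up is None or runner_up > best):
            bins[barcode_map[best_bc]].append(trimmed)
        else:
            bins["undetermined"].append(read)
    return bins


# ---------------------------------------------------------------------------
# amplicon assignment


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of matching one read against the panel."""

    amplicon: AmpliconSpec | None
    n_mismatches: int | None = None
    mismatch_frac: float | None = None
    reverse_complement: bool = False
    reason: str | None = None  # set when amplicon is None: "truncated"/"no_match"/"tie"

    @property
    def assigned(self) -> bool:
        return self.amplicon is not None


def _bisulfite_mismatches(read: np.ndarray, ref: np.ndarray) -> int:
    """Mismatch count treating every reference C as a C/T wildcard."""
    mism = read != ref
    c_ok = (ref == ord("C")) & (read == ord("T"))
    return int(np.count_nonzero(mism & ~c_ok))


def _seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def assign_to_amplicon(
    read_seq: str,
    panel: Sequence[AmpliconSpec],
    max_mismatch_frac: float = 0.10,
    try_reverse_complement: bool = True,
) -> AssignmentResult:
    """Assign a read to the amplicon it matches best, bisulfite-aware.

    Comparison is ungapped at offset 0 (amplicon reads are primer-anchored)
    over the overlap of read and reference; a reference ``C`` accepts read
    ``C`` or ``T``. The read is assigned to the amplicon with the fewest
    mismatches provided the mismatch fraction is at most
    ``max_mismatch_frac``; ties are left unassigned. A read too short to
    cover an amplicon's last CpG is "truncated" for that amplicon. If no
    forward match is found the reverse complement is tried and flagged.
    """
    if not panel:
        raise ValueError("empty amplicon panel")

    def _scan(seq: str) -> tuple[list[tuple[int, float, AmpliconSpec]], int]:
        arr = _seq_to_array(seq.upper())
        hits, n_truncated = [], 0
        for spec in panel:
            needed = (spec.cpg_offsets[-1] + 1) if spec.cpg_offsets else 1
            if len(arr) < needed:
                n_truncated += 1
                continue
            ref = _seq_to_array(spec.ref_seq)
            L = min(len(arr), len(ref))
            n_mm = _bisulfite_mismatches(arr[:L], ref[:L])
            frac = n_mm / L
            if frac <= max_mismatch_frac:
                hits.append((n_mm, frac, spec))
        return hits, n_truncated

    hits, n_trunc = _scan(read_seq)
    revcomp = False
    if not hits and try_reverse_complement:
        rc_hits, rc_trunc = _scan(reverse_complement(read_seq))
        if rc_hits:
            hits, revcomp = rc_hits, True
        n_trunc = max(n_trunc, rc_trunc)
    if not hits:
        reason = "truncated" if n_trunc == len(panel) else "no_match"
        return AssignmentResult(None, reason=reason)
    hits.sort(key=lambda t: t[0])
    if len(hits) > 1 and hits[1][0] == hits[0][0]:
        return AssignmentResult(None, reason="tie")
    n_mm, frac, spec = hits[0]
    return AssignmentResult(spec, n_mm, frac, reverse_complement=revcomp)


def assignment_stats(results: Iterable[AssignmentResult]) -> pd.Series:
    """Tally assignment outcomes (assigned per amplicon, plus failure reasons)."""
    counts: Counter[str] = Counter()
    for res in results:
        counts[res.amplicon.name if res.assigned else res.reason or "no_match"] += 1
    return pd.Series(counts, dtype=int).sort_index()
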