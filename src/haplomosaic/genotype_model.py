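"""Core data types and I/O for strain genotype panels.

The universal input is a :class:`GenotypeMatrix`: an ordered strain panel
genotyped at an ordered set of biallelic markers on one or more chromosomes.
Calls are stored as small integer codes relative to the *major/minor* allele
of each marker column:

====  =========================================
code  meaning
====  =========================================
 0    major allele (most frequent homozygous call)
 1    minor allele
 2    heterozygous
-1    missing / no call
====  =========================================

The major allele of a column is the nucleotide occurring most often among
non-heterozygous, non-missing calls; ties are broken toward the
lexicographically smaller nucleotide.  Complementing every column (swapping
major/minor labels consistently) does not change any downstream structure
that is built on allele *sharing* rather than allele identity.

Coordinates: marker indices are 0-based and per-chromosome; genomic
positions are 1-based inclusive (as displayed and as written to the
genotype table); BED output follows the BED standard (0-based, half-open).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: genotype codes
MAJOR = 0
MINOR = 1
HET = 2
MISSING = -1

_VALID_BASES = frozenset("ACGT")


class GenotypeFormatError(ValueError):
    """Malformed genotype input (ragged rows, bad call characters, ...)."""


class SortOrderError(ValueError):
    """Marker positions are not strictly increasing within a chromosome."""


@dataclass(frozen=True)
class Marker:
    """A biallelic SNP marker.

    ``index`` is the 0-based column index of the marker *within its
    chromosome*; ``pos`` is the 1-based base-pair coordinate.
    """

    chrom: str
    pos: int
    index: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"marker position must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class GenomicInterval:
    """A closed genomic interval in both coordinate systems.

    ``start_pos``/``end_pos`` are 1-based inclusive base-pair bounds;
    ``start_idx``/``end_idx`` are 0-based inclusive marker-index bounds.
    """

    chrom: str
    start_pos: int
    end_pos: int
    start_idx: int
    end_idx: int

    def __post_init__(self) -> None:
        if self.start_pos > self.end_pos:
            raise ValueError(
                f"interval start {self.start_pos} > end {self.end_pos}")
        if self.start_idx > self.end_idx:
            raise ValueError(
                f"interval start_idx {self.start_idx} > end_idx {self.end_idx}")

    @property
    def n_markers(self) -> int:
        return self.end_idx - self.start_idx + 1

    def contains_pos(self, pos: int) -> bool:
        return self.start_pos <= pos <= self.end_pos


@dataclass(frozen=True)
class SDP:
    """Strain distribution pattern: one binarized marker column.

    ``pattern`` holds one code per strain in {0, 1, 2, -1}.
    """

    marker_index: int
    pattern: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "pattern",
                           np.asarray(self.pattern, dtype=np.int8))


@dataclass
class GenotypeMatrix:
    """Strains x markers panel of biallelic genotype codes.

    ``calls`` has shape ``(n_strains, n_markers)``; ``allele_labels`` maps
    each marker column to its (major, minor) nucleotide pair.  A
    monomorphic column stores ``'.'`` as its minor label.
    """

    strains: list[str]
    markers: list[Marker]
    calls: np.ndarray
    allele_labels: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.strains), len(self.markers)):
            raise GenotypeFormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.strains)} strains x {len(self.markers)} markers")
        if len(self.allele_labels) != len(self.markers):
            raise GenotypeFormatError("one allele label pair per marker required")
        if len(set(self.strains)) != len(self.strains):
            raise GenotypeFormatError("strain names must be unique")
        bad = ~np.isin(self.calls, (MAJOR, MINOR, HET, MISSING))
        if bad.any():
            raise GenotypeFormatError("genotype codes restricted to {-1,0,1,2}")
        _check_sorted(self.markers)

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chroms(self) -> list[str]:
        out: list[str] = []
        for m in self.markers:
            if not out or out[-1] != m.chrom:
                out.append(m.chrom)
        return out

    def strain_index(self, name: str) -> int:
        try:
            return self.strains.index(name)
        except ValueError:
            raise KeyError(f"unknown strain name: {name!r}") from None

    def positions(self) -> np.ndarray:
        return np.array([m.pos for m in self.markers], dtype=np.int64)


def _check_sorted(markers: Sequence[Marker]) -> None:
    seen_chroms: set[str] = set()
    prev_chrom: str | None = None
    prev_pos = 0
    idx = 0
    for m in markers:
        if m.chrom != prev_chrom:
            if m.chrom in seen_chroms:
                raise SortOrderError(
                    f"chromosome {m.chrom} appears in non-contiguous blocks")
            seen_chroms.add(m.chrom)
            prev_chrom = m.chrom
            prev_pos = 0
            idx = 0
        if m.pos <= prev_pos:
            raise SortOrderError(
                f"positions not strictly increasing on {m.chrom}: "
                f"{prev_pos} then {m.pos}")
        if m.index != idx:
            raise SortOrderError(
                f"marker index {m.index} out of order on {m.chrom} "
                f"(expected {idx})")
        prev_pos = m.pos
        idx += 1


# ---------------------------------------------------------------------------
# construction from nucleotide letters (shared by table reader and simulator)

def matrix_from_letters(strains: Sequence[str], chroms: Sequence[str],
                        positions: Sequence[int],
                        letters: np.ndarray) -> GenotypeMatrix:
    """Build a matrix from per-strain nucleotide calls.

    ``letters`` is (n_strains, n_markers) of single characters in
    A/C/G/T (homozygous), H (heterozygous) or N (missing).  Each column is
    binarized with the major/minor convention.
    """
    letters = np.asarray(letters, dtype="U1")
    n_strains, n_markers = letters.shape
    calls = np.empty((n_strains, n_markers), dtype=np.int8)
    allele_labels: list[tuple[str, str]] = []
    for j in range(n_markers):
        col = letters[:, j]
        bases: dict[str, int] = {}
        for c in col:
            if c in _VALID_BASES:
                bases[c] = bases.get(c, 0) + 1
            elif c not in ("H", "N"):
                raise GenotypeFormatError(
                    f"invalid call character {c!r} in marker column {j}")
        if len(bases) > 2:
            raise GenotypeFormatError(
                f"marker column {j} has >2 alleles: {sorted(bases)}")
        if not bases:
            major, minor = ".", "."
        elif len(bases) == 1:
            major, minor = next(iter(bases)), "."
        else:
            (b1, n1), (b2, n2) = sorted(bases.items())
            # more frequent -> major; tie -> lexicographically smaller
            major, minor = (b1, b2) if n1 >= n2 else (b2, b1)
        code = np.full(n_strains, MISSING, dtype=np.int8)
        code[col == "H"] = HET
        if major != ".":
            code[col == major] = MAJOR
        if minor != ".":
            code[col == minor] = MINOR
        calls[:, j] = code
        allele_labels.append((major, minor))
    markers = _make_markers(chroms, positions)
    return GenotypeMatrix(list(strains), markers, calls, allele_labels)


def _make_markers(chroms: Sequence[str], positions: Sequence[int]) -> list[Marker]:
    markers: list[Marker] = []
    idx = 0
    prev: str | None = None
    for c, p in zip(chroms, positions):
        if c != prev:
            idx = 0
            prev = c
        markers.append(Marker(chrom=str(c), pos=int(p), index=idx))
        idx += 1
    return markers


# ---------------------------------------------------------------------------
# readers / writers

def read_genotype_matrix(path: str | os.PathLike,
                         format: str = "table") -> GenotypeMatrix:
    """Read a genotype panel from a tab-separated table or a VCF.

    Table layout: line 1 = chromosome per marker column, line 2 = position
    per marker column (each preceded by a label cell), then one row per
    strain: name followed by one call letter per marker (A/C/G/T/H/N).
    """
    if format == "table":
        return _read_table(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_table(path: str | os.PathLike) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise GenotypeFormatError(f"empty or truncated genotype table: {path}")
    chrom_row = lines[0].split("\t")
    pos_row = lines[1].split("\t")
    if len(chrom_row) != len(pos_row):
        raise GenotypeFormatError("chrom and pos header rows differ in length")
    chroms = chrom_row[1:]
    try:
        positions = [int(p) for p in pos_row[1:]]
    except ValueError as e:
        raise GenotypeFormatError(f"non-integer position in header: {e}") from None
    n_markers = len(chroms)
    strains: list[str] = []
    rows: list[list[str]] = []
    for lineno, ln in enumerate(lines[2:], start=3):
        fields = ln.split("\t")
        if len(fields) != n_markers + 1:
            raise GenotypeFormatError(
                f"row for strain {fields[0]!r} (line {lineno}) has "
                f"{len(fields) - 1} calls, expected {n_markers}")
        strains.append(fields[0])
        rows.append(fields[1:])
    letters = np.array(rows, dtype="U1")
    return matrix_from_letters(strains, chroms, positions, letters)


def write_genotype_table(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write the tab-separated genotype table (inverse of the table reader)."""
    code_to_letter = np.empty((matrix.n_markers, 4), dtype="U1")
    for j, (major, minor) in enumerate(matrix.allele_labels):
        # row layout indexed by code+1: missing, major, minor, het
        code_to_letter[j] = ("N", major if major != "." else "N",
                            minor if minor != "." else "N", "H")
    with open(path, "w") as fh:
        fh.write("chrom\t" + "\t".join(m.chrom for m in matrix.markers) + "\n")
        fh.write("pos\t" + "\t".join(str(m.pos) for m in matrix.markers) + "\n")
        for i, name in enumerate(matrix.strains):
            letters = [code_to_letter[j, matrix.calls[i, j] + 1]
                       for j in range(matrix.n_markers)]
            fh.write(name + "\t" + "\t".join(letters) + "\n")


def _read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    import pysam

    with pysam.VariantFile(os.fspath(path)) as vf:
        strains = list(vf.header.samples)
        chroms: list[str] = []
        positions: list[int] = []
        columns: list[np.ndarray] = []
        n_records = 0
        for rec in vf:
            n_records += 1
            alts = rec.alts or ()
            if (len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1
                    or rec.ref not in _VALID_BASES or alts[0] not in _VALID_BASES):
                logger.warning(
                    "skipping non-biallelic-SNP record %s:%s", rec.chrom, rec.pos)
                continue
            col = np.empty(len(strains), dtype="U1")
            for i, name in enumerate(strains):
                gt = rec.samples[name].get("GT")
                if gt is None or any(a is None for a in gt):
                    col[i] = "N"
                elif len(set(gt)) > 1:
                    col[i] = "H"
                else:
                    col[i] = rec.ref if gt[0] == 0 else alts[0]
            chroms.append(rec.chrom)
            positions.append(rec.pos)
            columns.append(col)
    if n_records == 0:
        raise GenotypeFormatError(f"empty VCF: {path}")
    if not columns:
        raise GenotypeFormatError(f"no biallelic SNP records in VCF: {path}")
    letters = np.stack(columns, axis=1)
    return matrix_from_letters(strains, chroms, positions, letters)


def write_intervals_bed(intervals: Iterable[tuple[GenomicInterval, str]],
                        path: str | os.PathLike,
                        scores: Sequence[int] | None = None) -> None:
    """Write labeled intervals as standard BED (0-based, half-open).

    Internal 1-based inclusive bounds convert as start-1, end unchanged.
    """
    items = list(intervals)
    with open(path, "w") as fh:
        for k, (iv, label) in enumerate(items):
            fields = [iv.chrom, str(iv.start_pos - 1), str(iv.end_pos), label]
            if scores is not None:
                fields.append(str(scores[k]))
            fh.write("\t".join(fields) + "\n")


def read_strain_metadata(path: str | os.PathLike) -> dict[str, dict[str, str]]:
    """Read the strain metadata table: strain, class, subspecies (may be blank).

    ``class`` is one of classical, wild_derived, wild_caught.
    """
    out: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            fields = ln.split("\t")
            if len(fields) < 2:
                raise GenotypeFormatError(f"bad metadata row: {ln!r}")
            strain, klass = fields[0], fields[1]
            subspecies = fields[2] if len(fields) > 2 else ""
            out[strain] = {"class": klass, "subspecies": subspecies}
    return out


# ---------------------------------------------------------------------------
# matrix operations

def sdp_at(matrix: GenotypeMatrix, marker_index: int) -> SDP:
    """The strain distribution pattern (binarized column) at one marker."""
    if not 0 <= marker_index < matrix.n_markers:
        raise IndexError(
            f"marker index {marker_index} out of range "
            f"[0, {matrix.n_markers})")
    return SDP(marker_index=marker_index,
               pattern=matrix.calls[:, marker_index].copy())


def subset(matrix: GenotypeMatrix, strain_names: Sequence[str],
           region: GenomicInterval | None = None) -> GenotypeMatrix:
    """Row/column slice: requested strains (in the requested order) and,
    optionally, only markers inside ``region`` (matched by chromosome and
    1-based inclusive position bounds)."""
    rows = [matrix.strain_index(s) for s in strain_names]
    if region is None:
        cols = list(range(matrix.n_markers))
    else:
        cols = [j for j, m in enumerate(matrix.markers)
                if m.chrom == region.chrom and region.contains_pos(m.pos)]
    markers = _make_markers([matrix.markers[j].chrom for j in cols],
                            [matrix.markers[j].pos for j in cols])
    return GenotypeMatrix(
        strains=[matrix.strains[i] for i in rows],
        markers=markers,
        calls=matrix.calls[np.ix_(rows, cols)],
        allele_labels=[matrix.allele_labels[j] for j in cols],
    )


def split_by_chromosome(matrix: GenotypeMatrix) -> dict[str, GenotypeMatrix]:
    """One single-chromosome matrix per chromosome, preserving marker order.

    Analyses run per chromosome; multi-chromosome inputs are split with this
    helper and processed independently.
    """
    out: dict[str, GenotypeMatrix] = {}
    for chrom in matrix.chroms:
        cols = [j for j, m in enumerate(matrix.markers) if m.chrom == chrom]
        out[chrom] = GenotypeMatrix(
            strains=list(matrix.strains),
            markers=[replace(matrix.markers[j]) for j in cols],
            calls=matrix.calls[:, cols],
            allele_labels=[matrix.allele_labels[j] for j in cols],
        )
    return out


def require_single_chromosome(matrix: GenotypeMatrix) -> str:
    chroms = matrix.chroms
    if len(chroms) != 1:
        raise ValueError(
            f"operation requires a single-chromosome matrix; got {chroms}; "
            "use split_by_chromosome first")
    return chroms[0]
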