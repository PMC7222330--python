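"""Alignment and annotation I/O: aligned FASTA, MAF regions, BED features.

All genomic coordinates are 0-based half-open (BED convention); MAF
start/size fields are converted on read. Sequences are uppercased and any
IUPAC ambiguity code other than N is mapped to N (the likelihood engine
observes only A, C, G, T; N and '-' are missing data).
"""

from __future__ import annotations

import bisect
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

logger = logging.getLogger("adaptiphy")

__all__ = [
    "NucAlignment",
    "FeatureSet",
    "Region",
    "AlignmentError",
    "EmptyAlignmentError",
    "MafParseError",
    "read_fasta_alignment",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_maf_region",
    "mask_features",
]

_VALID = set("ACGTN-")
_AMBIG = re.compile(r"[RYSWKMBDHVUrsywkmbdhvu]")
_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


class AlignmentError(ValueError):
    """Contract violation on an alignment operation."""


class EmptyAlignmentError(AlignmentError):
    """A requested region overlaps no aligned sequence."""


class MafParseError(AlignmentError):
    """Malformed MAF input."""


@dataclass(frozen=True)
class Region:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _normalize(seq: str, context: str = "") -> str:
    s = seq.upper().replace("U", "T")
    if _AMBIG.search(seq):
        logger.warning("ambiguity codes mapped to N%s", f" in {context}" if context else "")
        s = _AMBIG.sub("N", s)
    bad = set(s) - _VALID
    if bad:
        raise AlignmentError(f"invalid characters {sorted(bad)}{' in ' + context if context else ''}")
    return s


@dataclass
class NucAlignment:
    """Gap-aware multi-species aligned nucleotide matrix.

    ``coord`` locates the alignment on ``ref_species`` (which must then be
    one of ``species``); ``meta`` carries free-form provenance.
    """

    species: list[str]
    seqs: list[str]
    coord: Optional[Region] = None
    ref_species: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.species) != len(self.seqs):
            raise AlignmentError("species/sequence count mismatch")
        if len(set(self.species)) != len(self.species):
            raise AlignmentError("duplicate species names")
        if not self.seqs or not self.seqs[0]:
            raise AlignmentError("empty alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        self.seqs = [
            _normalize(s, context=name) for name, s in zip(self.species, self.seqs)
        ]
        if self.coord is not None:
            if self.ref_species is None:
                self.ref_species = self.species[0]
            if self.ref_species not in self.species:
                raise AlignmentError(
                    f"reference species {self.ref_species!r} not in alignment"
                )

    # -- basic queries -------------------------------------------------

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    @property
    def n_species(self) -> int:
        return len(self.species)

    def get(self, name: str) -> str:
        return self.seqs[self.species.index(name)]

    def matrix(self) -> np.ndarray:
        """(n_species, length) array of single characters."""
        return np.array([list(s) for s in self.seqs], dtype="U1")

    def missing_fractions(self) -> dict[str, float]:
        """Per-species fraction of N/gap cells."""
        return {
            name: (s.count("N") + s.count("-")) / len(s)
            for name, s in zip(self.species, self.seqs)
        }

    # -- coordinate bookkeeping ---------------------------------------

    def ref_positions(self) -> np.ndarray:
        """Reference-species coordinate per column; -1 where the
        reference carries a gap (gap columns have no coordinate)."""
        if self.coord is None:
            raise AlignmentError("alignment carries no coordinates")
        ref = self.get(self.ref_species)
        pos = np.full(self.length, -1, dtype=int)
        cursor = self.coord.start
        for i, ch in enumerate(ref):
            if ch != "-":
                pos[i] = cursor
                cursor += 1
        return pos

    # -- derived alignments -------------------------------------------

    def take_columns(self, cols) -> "NucAlignment":
        cols = np.asarray(cols, dtype=int)
        if cols.size == 0:
            raise EmptyAlignmentError("no columns selected")
        seqs = ["".join(s[c] for c in cols) for s in self.seqs]
        return NucAlignment(
            list(self.species), seqs, coord=None, ref_species=self.ref_species,
            meta=dict(self.meta),
        )

    def subregion(self, start: int, end: int) -> "NucAlignment":
        """Columns whose reference coordinate lies in [start, end); gap
        columns interior to the span are carried along."""
        pos = self.ref_positions()
        inside = (pos >= start) & (pos < end)
        if not inside.any():
            raise EmptyAlignmentError(
                f"no aligned columns in {self.coord.chrom}:{start}-{end}"
            )
        first, last = np.nonzero(inside)[0][[0, -1]]
        cols = np.arange(first, last + 1)
        out = self.take_columns(cols)
        real = pos[inside]
        out.coord = Region(self.coord.chrom, int(real.min()), int(real.max()) + 1)
        out.ref_species = self.ref_species
        return out

    @classmethod
    def concat(cls, parts: Iterable["NucAlignment"]) -> "NucAlignment":
        parts = list(parts)
        if not parts:
            raise AlignmentError("nothing to concatenate")
        species = parts[0].species
        for p in parts[1:]:
            if p.species != species:
                raise AlignmentError("species mismatch in concatenation")
        seqs = ["".join(p.seqs[i] for p in parts) for i in range(len(species))]
        meta = {"segments": [p.meta.get("segment") or p.coord for p in parts]}
        return cls(list(species), seqs, meta=meta)


# -- FASTA ------------------------------------------------------------


def read_fasta_alignment(path) -> NucAlignment:
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    names = [r.id for r in records]
    return NucAlignment(names, [str(r.seq) for r in records])


def write_fasta(aln: NucAlignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="")
        for name, s in zip(aln.species, aln.seqs)
    ]
    SeqIO.write(records, path, "fasta")


# -- BED --------------------------------------------------------------


@dataclass
class FeatureSet:
    """Set of (chrom, start, end) intervals, 0-based half-open."""

    intervals: set[tuple[str, int, int]]
    label: str = ""

    def __post_init__(self):
        for chrom, start, end in self.intervals:
            if start < 0 or start >= end:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")
        self._merged_cache: dict | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def merged(self) -> dict[str, list[tuple[int, int]]]:
        """Per-chromosome merged, sorted intervals."""
        if self._merged_cache is None:
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for chrom, start, end in sorted(self.intervals):
                ivs = by_chrom.setdefault(chrom, [])
                if ivs and start <= ivs[-1][1]:
                    ivs[-1] = (ivs[-1][0], max(ivs[-1][1], end))
                else:
                    ivs.append((start, end))
            self._merged_cache = by_chrom
        return self._merged_cache

    def covers(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: which positions fall inside a feature."""
        positions = np.asarray(positions)
        out = np.zeros(positions.shape, dtype=bool)
        ivs = self.merged().get(chrom)
        if not ivs:
            return out
        starts = [s for s, _ in ivs]
        for i, p in enumerate(positions.ravel()):
            if p < 0:
                continue
            j = bisect.bisect_right(starts, p) - 1
            if j >= 0 and p < ivs[j][1]:
                out.flat[i] = True
        return out


def read_bed(path, label: str = "") -> FeatureSet:
    intervals = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: bad interval {start}-{end}")
            intervals.add((chrom, start, end))
    return FeatureSet(intervals, label=label or str(path))


def write_bed(features: FeatureSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in sorted(features.intervals):
            fh.write(f"{chrom}\t{start}\t{end}\n")


# -- MAF --------------------------------------------------------------


def _split_src(src: str) -> tuple[str, str]:
    if "." in src:
        sp, chrom = src.split(".", 1)
    else:
        sp, chrom = src, ""
    return sp, chrom


def read_maf_region(path, species: list[str], region: Region) -> NucAlignment:
    """Stitch a sub-alignment for ``region`` out of a MAF file.

    The first entry of ``species`` is the reference species; blocks are
    located via its coordinates, which must be plus-strand genomic.
    Species absent from a block contribute gaps for that block's span.
    """

    if not species:
        raise ValueError("empty species list")
    ref = species[0]
    pieces = []  # (ref_start, {species: seq})
    try:
        blocks = list(AlignIO.parse(path, "maf"))
    except ValueError as exc:
        raise MafParseError(f"{path}: {exc}") from exc

    for bi, block in enumerate(blocks):
        rows = {}
        annot = {}
        for rec in block:
            sp, chrom = _split_src(rec.id)
            if sp not in species:
                continue
            rows[sp] = str(rec.seq)
            annot[sp] = (chrom, rec.annotations)
        if ref not in rows:
            continue
        chrom, ra = annot[ref]
        if chrom != region.chrom:
            continue
        if ra.get("strand", 1) == -1:
            # flip the whole block onto the reference-forward strand
            start = ra["srcSize"] - (ra["start"] + ra["size"])
            rows = {
                sp: seq[::-1].translate(_COMPLEMENT) for sp, seq in rows.items()
            }
        else:
            start = ra["start"]
        ncols = len(rows[ref])
        for sp, seq in rows.items():
            if len(seq) != ncols:
                raise MafParseError(f"{path}: ragged block #{bi + 1}")
        refseq = rows[ref]
        # reference coordinate per column
        pos = np.full(ncols, -1, dtype=int)
        cursor = start
        for i, ch in enumerate(refseq):
            if ch != "-":
                pos[i] = cursor
                cursor += 1
        inside = (pos >= region.start) & (pos < region.end)
        if not inside.any():
            continue
        idx = np.nonzero(inside)[0]
        cols = slice(int(idx[0]), int(idx[-1]) + 1)
        width = cols.stop - cols.start
        piece = {
            sp: rows.get(sp, "-" * ncols)[cols] for sp in species
        }
        pieces.append((int(pos[inside].min()), int(pos[inside].max()) + 1, piece, width))

    if not pieces:
        raise EmptyAlignmentError(
            f"no MAF blocks overlap {region.chrom}:{region.start}-{region.end}"
        )
    pieces.sort(key=lambda p: p[0])
    seqs = {sp: [] for sp in species}
    for _, _, piece, _ in pieces:
        for sp in species:
            seqs[sp].append(piece[sp])
    start = pieces[0][0]
    end = pieces[-1][1]
    aln = NucAlignment(
        list(species),
        ["".join(seqs[sp]) for sp in species],
        coord=Region(region.chrom, start, end),
        ref_species=ref,
    )
    aln.meta["missing_fractions"] = aln.missing_fractions()
    return aln


# -- feature masking --------------------------------------------------


def mask_features(aln: NucAlignment, features: FeatureSet) -> NucAlignment:
    """Replace every column whose reference coordinate falls in a feature
    with N in all rows (the ``maf_parse --mask-features`` behaviour).

    Columns that are gaps in the reference have no coordinate and are
    never masked. Idempotent; column count is unchanged.
    """
    if aln.coord is None:
        raise AlignmentError("mask_features requires a located alignment")
    if not features.intervals:
        return NucAlignment(
            list(aln.species), list(aln.seqs), coord=aln.coord,
            ref_species=aln.ref_species, meta=dict(aln.meta),
        )
    pos = aln.ref_positions()
    hit = features.covers(aln.coord.chrom, pos)
    if not hit.any():
        masked = list(aln.seqs)
    else:
        mat = aln.matrix()
        mat[:, hit] = "N"
        masked = ["".join(row) for row in mat]
    return NucAlignment(
        list(aln.species), masked, coord=aln.coord,
        ref_species=aln.ref_species, meta=dict(aln.meta),
    )
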