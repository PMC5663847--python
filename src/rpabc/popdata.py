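"""Data model and I/O for microsatellite genotypes, mtDNA alignments and population partitions.

Conventions
-----------
* Microsatellite allele sizes are stored internally in **repeat units** (positive
  integers).  Inputs expressed in base pairs are divided by the locus motif length;
  a non-integral division is a hard error rather than a silent rounding.
* A missing genotype is an absent *pair*: either both alleles of an individual at a
  locus are typed or neither is.  Internally missing cells carry the sentinel ``-1``
  in the allele array but the sentinel never leaks into statistics — use
  :meth:`GenotypeTable.typed_mask`.
* Individuals present only in the mtDNA alignment (no nuclear genotypes) are legal
  and participate only in sequence statistics.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = -1
DNA_ALPHABET = frozenset("ACGT")


class PopDataError(ValueError):
    """Malformed input data or violated data-model invariant."""


@dataclass
class GenotypeTable:
    """Diploid allele-size matrix (individuals x loci x 2) in repeat units.

    ``alleles[i, l]`` is the unordered pair of allele sizes of individual ``i`` at
    locus ``l``, or ``(-1, -1)`` when the locus is untyped for that individual.
    """

    individual_ids: list[str]
    locus_names: list[str]
    alleles: np.ndarray  # (n, L, 2) int
    motif_lengths: list[int] | None = None
    locality: list[str] | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=int)
        n, L = len(self.individual_ids), len(self.locus_names)
        if L < 1:
            raise PopDataError("a genotype table needs at least one locus")
        if self.alleles.shape != (n, L, 2):
            raise PopDataError(
                f"allele array shape {self.alleles.shape} != ({n}, {L}, 2)")
        if len(set(self.individual_ids)) != n:
            raise PopDataError("duplicate individual ids")
        if self.motif_lengths is None:
            self.motif_lengths = [1] * L
        if len(self.motif_lengths) != L:
            raise PopDataError("motif_lengths length mismatch")
        half = self.alleles == MISSING
        if np.any(half[..., 0] != half[..., 1]):
            raise PopDataError("half-missing genotype: both alleles of a pair "
                               "must be typed or both missing")
        if np.any((self.alleles <= 0) & ~half):
            raise PopDataError("allele sizes must be positive integers")
        if self.locality is not None and len(self.locality) != n:
            raise PopDataError("locality length mismatch")

    # -- masks and counts ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def typed_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the genotype is present."""
        return self.alleles[..., 0] != MISSING

    def typed_loci_per_individual(self) -> np.ndarray:
        return self.typed_mask().sum(axis=1)

    def missing_fraction(self) -> np.ndarray:
        """Per-locus fraction of untyped individuals, in [0, 1]."""
        return 1.0 - self.typed_mask().mean(axis=0)

    def subset(self, individuals: Sequence[str]) -> "GenotypeTable":
        index = {ind: i for i, ind in enumerate(self.individual_ids)}
        rows = [index[i] for i in individuals]
        return GenotypeTable(
            individual_ids=list(individuals),
            locus_names=list(self.locus_names),
            alleles=self.alleles[rows].copy(),
            motif_lengths=list(self.motif_lengths),
            locality=[self.locality[r] for r in rows] if self.locality else None,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.locus_names == other.locus_names
            and self.motif_lengths == other.motif_lengths
            and self.locality == other.locality
            and np.array_equal(np.sort(self.alleles, axis=2),
                               np.sort(other.alleles, axis=2))
        )


@dataclass
class HaplotypeAlignment:
    """Equal-length aligned haploid sequences (mtDNA control region)."""

    individual_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.individual_ids) != len(self.sequences):
            raise PopDataError("ids/sequences length mismatch")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise PopDataError("duplicate sequence ids")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise PopDataError(f"unequal sequence lengths: {sorted(lengths)}")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def _byte_matrix(self) -> np.ndarray:
        return np.frombuffer("".join(self.sequences).encode("ascii"),
                             dtype="S1").reshape(self.n_sequences, self.length)

    def excluded_sites(self) -> np.ndarray:
        """Indices of columns containing any non-ACGT symbol (gaps, ambiguities).

        These columns are excluded listwise from every sequence statistic.
        """
        if not self.sequences:
            return np.empty(0, dtype=int)
        mat = self._byte_matrix()
        bad = ~np.isin(mat, [b"A", b"C", b"G", b"T"])
        return np.nonzero(bad.any(axis=0))[0]

    def as_matrix(self, drop_excluded: bool = True) -> np.ndarray:
        """Single-byte character matrix (n, L'), optionally restricted to the
        clean ACGT columns.  Cached: alignments are immutable by convention.
        """
        key = "_mat_clean" if drop_excluded else "_mat_full"
        cached = self.__dict__.get(key)
        if cached is not None:
            return cached
        mat = self._byte_matrix()
        if drop_excluded and mat.size:
            keep = np.ones(mat.shape[1], dtype=bool)
            keep[self.excluded_sites()] = False
            mat = mat[:, keep]
        self.__dict__[key] = mat
        return mat

    def subset(self, individuals: Sequence[str]) -> "HaplotypeAlignment":
        index = {ind: i for i, ind in enumerate(self.individual_ids)}
        rows = [index[i] for i in individuals]
        return HaplotypeAlignment(list(individuals),
                                  [self.sequences[r] for r in rows])


@dataclass
class PopulationPartition:
    """Assignment of individuals to disjoint population labels."""

    assignment: dict[str, str]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = list(dict.fromkeys(self.assignment.values()))
        if not self.labels:
            self.labels = seen
        extra = set(seen) - set(self.labels)
        if extra:
            raise PopDataError(f"assignment uses undeclared labels: {sorted(extra)}")

    def members(self, label: str, universe: Sequence[str]) -> list[str]:
        """Individuals of ``universe`` assigned to ``label`` (in universe order)."""
        return [i for i in universe if self.assignment.get(i) == label]

    def validate_against(self, geno: GenotypeTable | None,
                         mt: HaplotypeAlignment | None) -> None:
        known: set[str] = set()
        if geno is not None:
            known |= set(geno.individual_ids)
        if mt is not None:
            known |= set(mt.individual_ids)
        orphans = sorted(set(self.assignment) - known)
        if orphans:
            raise PopDataError(f"partition labels unknown individuals: {orphans}")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _to_repeat_units(size: int, motif: int, units: str, locus: str) -> int:
    if size == 0:
        return MISSING
    if units == "repeats" or motif == 1:
        return size
    if size % motif:
        raise PopDataError(
            f"allele size {size} at locus {locus} is not a multiple of "
            f"motif length {motif}")
    return size // motif


def read_genotypes(path: str | Path, format: str = "genepop", *,
                   motif_lengths: Sequence[int] | None = None,
                   units: str = "repeats") -> GenotypeTable:
    """Read a genotype table from a GenePop or CSV file.

    Parameters
    ----------
    format:
        ``"genepop"`` (4- or 6-digit dialect) or ``"csv"`` (columns
        ``id, locality, <locus>_a, <locus>_b, ...``).
    motif_lengths:
        Repeat-motif length per locus in base pairs; required when
        ``units="bp"`` so sizes can be converted to repeat units.
    units:
        ``"repeats"`` (sizes stored as given) or ``"bp"`` (divide by motif).
    """
    if format not in {"genepop", "csv"}:
        raise PopDataError(f"unknown genotype format {format!r}")
    if units not in {"repeats", "bp"}:
        raise PopDataError(f"unknown units {units!r}")
    text = Path(path).read_text()
    if format == "genepop":
        table = _parse_genepop(text, path)
    else:
        table = _parse_genotype_csv(text, path)
    if motif_lengths is not None:
        if len(motif_lengths) != table.n_loci:
            raise PopDataError("motif_lengths does not match locus count")
        table.motif_lengths = list(motif_lengths)
    if units == "bp":
        if motif_lengths is None:
            raise PopDataError("units='bp' requires motif_lengths")
        conv = np.array(table.alleles)
        for l, (name, motif) in enumerate(zip(table.locus_names,
                                              table.motif_lengths)):
            for idx in np.ndindex(conv.shape[0], 2):
                conv[idx[0], l, idx[1]] = _to_repeat_units(
                    int(table.alleles[idx[0], l, idx[1]]
                        if table.alleles[idx[0], l, idx[1]] != MISSING else 0),
                    motif, "bp", name)
        table.alleles = conv
    return table


def _parse_genepop(text: str, path: str | Path) -> GenotypeTable:
    lines = text.splitlines()
    if len(lines) < 3:
        raise PopDataError(f"{path}: not a GenePop file (too short)")
    body = lines[1:]
    locus_names: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        part = body[i].strip()
        if part:
            locus_names.extend(n.strip() for n in part.split(",") if n.strip())
        i += 1
    if i == len(body):
        raise PopDataError(f"{path}: no 'Pop' line found")
    ids: list[str] = []
    locality: list[str] = []
    rows: list[list[int]] = []
    pop_index = 0
    pop_name = "pop0"
    for lineno, line in enumerate(body[i:], start=i + 2):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            pop_index += 1
            pop_name = f"pop{pop_index}"
            continue
        if "," not in stripped:
            raise PopDataError(f"{path}:{lineno}: expected 'id , genotypes'")
        ind_id, geno_part = stripped.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != len(locus_names):
            raise PopDataError(
                f"{path}:{lineno}: {len(tokens)} genotypes for "
                f"{len(locus_names)} loci")
        row: list[int] = []
        for tok, locus in zip(tokens, locus_names):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise PopDataError(
                    f"{path}:{lineno}: genotype {tok!r} at {locus} is not a "
                    "4- or 6-digit code")
            half = len(tok) // 2
            a, b = int(tok[:half]), int(tok[half:])
            if (a == 0) != (b == 0):
                raise PopDataError(
                    f"{path}:{lineno}: half-missing genotype {tok!r} at {locus}")
            row.extend([a or MISSING, b or MISSING])
        ids.append(ind_id.strip())
        locality.append(pop_name)
        rows.append(row)
    alleles = np.array(rows, dtype=int).reshape(len(ids), len(locus_names), 2)
    return GenotypeTable(ids, locus_names, alleles, locality=locality)


def _parse_genotype_csv(text: str, path: str | Path) -> GenotypeTable:
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise PopDataError(f"{path}: empty CSV") from None
    if len(header) < 4 or header[0] != "id" or header[1] != "locality":
        raise PopDataError(f"{path}: expected header 'id,locality,<locus>_a,...'")
    allele_cols = header[2:]
    if len(allele_cols) % 2:
        raise PopDataError(f"{path}: odd allele column count")
    locus_names = []
    for k in range(0, len(allele_cols), 2):
        a, b = allele_cols[k], allele_cols[k + 1]
        stem = re.sub(r"_a$", "", a)
        if a != f"{stem}_a" or b != f"{stem}_b":
            raise PopDataError(f"{path}: columns {a!r},{b!r} are not a "
                               "<locus>_a/<locus>_b pair")
        locus_names.append(stem)
    ids, locality, rows = [], [], []
    for lineno, rec in enumerate(reader, start=2):
        if not rec or not any(rec):
            continue
        if len(rec) != len(header):
            raise PopDataError(f"{path}:{lineno}: wrong field count")
        ids.append(rec[0])
        locality.append(rec[1])
        row = []
        for k in range(2, len(rec), 2):
            cell = (rec[k].strip(), rec[k + 1].strip())
            if cell in {("0", "0"), ("", ""), ("NA", "NA")}:
                row.extend([MISSING, MISSING])
            else:
                try:
                    a, b = int(cell[0]), int(cell[1])
                except ValueError:
                    raise PopDataError(
                        f"{path}:{lineno}: non-integer allele {cell}") from None
                if (a == 0) != (b == 0):
                    raise PopDataError(f"{path}:{lineno}: half-missing genotype")
                row.extend([a or MISSING, b or MISSING])
        rows.append(row)
    alleles = np.array(rows, dtype=int).reshape(len(ids), len(locus_names), 2)
    return GenotypeTable(ids, locus_names, alleles, locality=locality)


def write_genotypes(table: GenotypeTable, path: str | Path,
                    format: str = "genepop", title: str = "rpabc export") -> None:
    path = Path(path)
    if format == "genepop":
        width = 3 if int(table.alleles.max(initial=0)) > 99 else 2
        out = [title]
        out.extend(table.locus_names)
        localities = table.locality or ["pop1"] * table.n_individuals
        current = None
        for i, ind in enumerate(table.individual_ids):
            if localities[i] != current:
                out.append("Pop")
                current = localities[i]
            cells = []
            for l in range(table.n_loci):
                a, b = table.alleles[i, l]
                a = 0 if a == MISSING else a
                b = 0 if b == MISSING else b
                cells.append(f"{a:0{width}d}{b:0{width}d}")
            out.append(f"{ind} , " + " ".join(cells))
        path.write_text("\n".join(out) + "\n")
    elif format == "csv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            header = ["id", "locality"]
            for name in table.locus_names:
                header += [f"{name}_a", f"{name}_b"]
            w.writerow(header)
            localities = table.locality or [""] * table.n_individuals
            for i, ind in enumerate(table.individual_ids):
                row = [ind, localities[i]]
                for l in range(table.n_loci):
                    a, b = table.alleles[i, l]
                    row += [0 if a == MISSING else int(a),
                            0 if b == MISSING else int(b)]
                w.writerow(row)
    else:
        raise PopDataError(f"unknown genotype format {format!r}")


def read_haplotypes(path: str | Path) -> HaplotypeAlignment:
    """Read an aligned FASTA of mtDNA haplotypes (equal-length records)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise PopDataError(f"{path}: no FASTA records")
    return HaplotypeAlignment([r.id for r in records],
                              [str(r.seq) for r in records])


def write_haplotypes(aln: HaplotypeAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="")
               for i, s in zip(aln.individual_ids, aln.sequences)]
    SeqIO.write(records, str(path), "fasta")


def read_partition(path: str | Path) -> PopulationPartition:
    """CSV with columns ``id,population``."""
    assignment: dict[str, str] = {}
    order: list[str] = []
    with Path(path).open() as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["id", "population"]:
            raise PopDataError(f"{path}: expected header 'id,population'")
        for rec in reader:
            if not rec or not any(rec):
                continue
            assignment[rec[0]] = rec[1]
            if rec[1] not in order:
                order.append(rec[1])
    return PopulationPartition(assignment, order)


def write_partition(part: PopulationPartition, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "population"])
        for ind, pop in part.assignment.items():
            w.writerow([ind, pop])


# ---------------------------------------------------------------------------
# Individual-inclusion filter
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    kept: list[str]
    removed: list[tuple[str, str]]  # (id, reason)


def filter_individuals(geno: GenotypeTable, mt: HaplotypeAlignment | None
                       ) -> tuple[GenotypeTable, FilterReport]:
    """Apply the half-the-loci inclusion rule.

    An individual is retained iff it is typed at >= 6 microsatellite loci, or at
    >= 5 loci and also carries an mtDNA sequence ("at least 50% of the locus
    available" with the mtDNA counting as one locus of twelve).  Idempotent.
    """
    mt_ids = set(mt.individual_ids) if mt is not None else set()
    typed = geno.typed_loci_per_individual()
    kept, removed = [], []
    for i, ind in enumerate(geno.individual_ids):
        has_mt = ind in mt_ids
        if typed[i] >= 6 or (typed[i] >= 5 and has_mt):
            kept.append(ind)
        else:
            removed.append((ind, f"typed at {typed[i]}/{geno.n_loci} loci, "
                                 f"mtDNA {'present' if has_mt else 'absent'}"))
    return geno.subset(kept), FilterReport(kept, removed)
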