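"""Reading, validation and writing of SNP genotype matrices, genetic maps and
inbred-line derivation records.

All downstream statistics operate on :class:`PhasedGenotypeMatrix`, a dense
(individual, marker, haplotype) array of 0/1 allele calls with an attached
:class:`GeneticMap` in centimorgans. Genotypes travel either as VCF 4.x (GT
field only) or as a simple TSV dialect (one row per individual, cells like
``0|1``); the genetic map always travels as a separate TSV of
``marker_id, chromosome, position_cM`` because the analyses are carried out in
genetic distance, not physical coordinates.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GeneticMap",
    "PhasedGenotypeMatrix",
    "LineRecord",
    "GenotypeParseError",
    "GenotypeValidationError",
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "write_map",
    "read_lines",
    "write_lines",
]

#: Sentinel for a missing allele call in the allele array.
MISSING: int = -1

_TOOL_HEADER = "# selfdiv genotype tools v0.1.0"


class GenotypeParseError(ValueError):
    """A record could not be parsed (malformed file content)."""


class GenotypeValidationError(ValueError):
    """Parsed content violates a structural invariant (e.g. multi-allelic site)."""


@dataclass(frozen=True)
class GeneticMap:
    """Ordered SNP map: marker ids with chromosome and position in cM.

    Positions are absolute within each chromosome, 0-based at the chromosome
    start, and must be non-decreasing within a chromosome. Markers are stored
    in (chromosome, position) order, the order the genotype matrix follows.
    """

    marker_ids: tuple[str, ...]
    chromosomes: tuple[str, ...]
    positions_cM: np.ndarray  # float, shape (n_markers,)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_cM, dtype=float)
        object.__setattr__(self, "positions_cM", pos)
        if not (len(self.marker_ids) == len(self.chromosomes) == pos.size):
            raise GenotypeValidationError("map columns have unequal lengths")
        if pos.size == 0:
            raise GenotypeValidationError("empty genetic map")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise GenotypeValidationError("duplicate marker ids in map")
        if np.any(pos < 0):
            raise GenotypeValidationError("negative cM position in map")
        seen: dict[str, float] = {}
        order: list[str] = []
        for chrom, p in zip(self.chromosomes, pos):
            if chrom not in seen:
                seen[chrom] = p
                order.append(chrom)
            else:
                if order[-1] != chrom:
                    raise GenotypeValidationError(
                        f"markers of chromosome {chrom!r} are not contiguous"
                    )
                if p < seen[chrom]:
                    raise GenotypeValidationError(
                        f"cM positions decrease within chromosome {chrom!r}"
                    )
                seen[chrom] = p

    def __len__(self) -> int:
        return len(self.marker_ids)

    @property
    def chromosome_names(self) -> tuple[str, ...]:
        out: list[str] = []
        for c in self.chromosomes:
            if not out or out[-1] != c:
                out.append(c)
        return tuple(out)

    def chromosome_slices(self) -> dict[str, slice]:
        """Contiguous marker index slice per chromosome, in map order."""
        chroms = np.asarray(self.chromosomes)
        out: dict[str, slice] = {}
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[str(chroms[start])] = slice(start, i)
                start = i
        return out

    def index_of(self, marker_id: str) -> int:
        return self.marker_ids.index(marker_id)


@dataclass
class PhasedGenotypeMatrix:
    """Diploid biallelic genotype calls for a sample of individuals.

    ``alleles[i, m, k]`` is the k-th allele call (k in {0, 1}) of individual
    ``i`` at marker ``m``: 0 = REF, 1 = ALT, :data:`MISSING` = no call. When
    ``phased`` is False the within-individual haplotype ordering carries no
    information and phase-dependent operations must refuse the matrix.
    """

    individuals: list[str]
    alleles: np.ndarray  # int8, shape (n_individuals, n_markers, 2)
    phased: bool
    gmap: GeneticMap

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise GenotypeValidationError("allele array must have shape (n, m, 2)")
        if self.alleles.shape[0] != len(self.individuals):
            raise GenotypeValidationError("individual axis does not match sample list")
        if self.alleles.shape[1] != len(self.gmap):
            raise GenotypeValidationError(
                f"marker axis ({self.alleles.shape[1]}) does not match map "
                f"length ({len(self.gmap)})"
            )
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise GenotypeValidationError("allele calls must be 0, 1 or MISSING")

    @property
    def n_individuals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def subset(self, indices: Sequence[int]) -> "PhasedGenotypeMatrix":
        """New matrix restricted to the given individuals (order preserved)."""
        idx = list(indices)
        return PhasedGenotypeMatrix(
            individuals=[self.individuals[i] for i in idx],
            alleles=self.alleles[idx],
            phased=self.phased,
            gmap=self.gmap,
        )

    def require_phase(self, operation: str) -> None:
        if not self.phased:
            raise GenotypeValidationError(
                f"{operation} requires phased genotypes; this matrix is unphased "
                "(pseudo-phasing is never applied silently)"
            )


_VALID_STATUS = ("extinct", "censored")


@dataclass(frozen=True)
class LineRecord:
    """One inbred line: how many selfing generations it survived and whether it
    went extinct or reached the end of the assay (right-censored)."""

    line_id: str
    population: str
    block: str
    generations_survived: int
    status: str
    assay_length: int | None = None

    def __post_init__(self) -> None:
        if self.status not in _VALID_STATUS:
            raise GenotypeValidationError(
                f"unknown status {self.status!r} for line {self.line_id!r}; "
                f"expected one of {_VALID_STATUS}"
            )
        if self.generations_survived < 1:
            raise GenotypeValidationError(
                f"line {self.line_id!r}: generations_survived must be >= 1"
            )
        if self.assay_length is not None:
            if self.generations_survived > self.assay_length:
                raise GenotypeValidationError(
                    f"line {self.line_id!r} survived past the assay length"
                )
            if self.status == "censored" and self.generations_survived != self.assay_length:
                raise GenotypeValidationError(
                    f"censored line {self.line_id!r} must be censored at the assay end"
                )


# ---------------------------------------------------------------------------
# genetic map TSV


def read_map(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"marker_id": str, "chromosome": str})
    required = {"marker_id", "chromosome", "position_cM"}
    if not required.issubset(df.columns):
        raise GenotypeParseError(f"map file missing columns {sorted(required - set(df.columns))}")
    return GeneticMap(
        marker_ids=tuple(df["marker_id"]),
        chromosomes=tuple(df["chromosome"]),
        positions_cM=df["position_cM"].to_numpy(dtype=float),
    )


def write_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_TOOL_HEADER + "\n")
        fh.write("marker_id\tchromosome\tposition_cM\n")
        for mid, chrom, pos in zip(gmap.marker_ids, gmap.chromosomes, gmap.positions_cM):
            fh.write(f"{mid}\t{chrom}\t{pos:.6f}\n")


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(
    path: str | Path, format: str, gmap: GeneticMap | str | Path
) -> PhasedGenotypeMatrix:
    """Read a genotype matrix in ``vcf`` or ``tsv`` format against a genetic map.

    The map may be given as a :class:`GeneticMap` or a path to its TSV. Every
    marker in the genotype file must be present in the map; the matrix is
    returned in map order. Phase is inferred from the genotype separator
    (``|`` phased, ``/`` unphased) which must be consistent across the file.
    """
    if not isinstance(gmap, GeneticMap):
        gmap = read_map(gmap)
    if format == "vcf":
        ids, alleles, marker_ids, phased = _read_vcf(path)
    elif format == "tsv":
        ids, alleles, marker_ids, phased = _read_tsv(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")

    known = {m: i for i, m in enumerate(gmap.marker_ids)}
    missing_from_map = [m for m in marker_ids if m not in known]
    if missing_from_map:
        raise GenotypeValidationError(
            f"markers absent from the genetic map: {missing_from_map[:5]}"
            + ("..." if len(missing_from_map) > 5 else "")
        )
    order = np.argsort([known[m] for m in marker_ids], kind="stable")
    if len(marker_ids) != len(gmap):
        # genotyped markers may be a subset of the map; restrict the map
        keep = sorted(known[m] for m in marker_ids)
        gmap = GeneticMap(
            marker_ids=tuple(gmap.marker_ids[i] for i in keep),
            chromosomes=tuple(gmap.chromosomes[i] for i in keep),
            positions_cM=gmap.positions_cM[keep],
        )
    return PhasedGenotypeMatrix(
        individuals=ids, alleles=alleles[:, order, :], phased=phased, gmap=gmap
    )


def _read_vcf(path: str | Path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    phase_seen: set[bool] = set()
    for lineno, variant in enumerate(vcf, start=1):
        if len(variant.ALT) != 1:
            raise GenotypeValidationError(
                f"multi-allelic site {variant.CHROM}:{variant.POS} "
                f"(ID={variant.ID}) is not supported"
            )
        gts = np.array(variant.genotypes)  # (n, 3): a0, a1, phased flag
        if gts.shape[1] != 3:
            raise GenotypeParseError(f"non-diploid genotype at record {lineno}")
        calls = gts[:, :2].astype(np.int8)
        calls[calls < 0] = MISSING
        if calls.max(initial=0) > 1:
            raise GenotypeValidationError(
                f"allele index >1 at {variant.CHROM}:{variant.POS}"
            )
        # cyvcf2 reports phase per call; missing-genotype phase flags are
        # meaningless, so only informative calls vote.
        informative = (calls != MISSING).any(axis=1)
        for ph in np.unique(gts[informative, 2]):
            phase_seen.add(bool(ph))
        marker_ids.append(variant.ID if variant.ID else f"{variant.CHROM}:{variant.POS}")
        rows.append(calls)
    if not rows:
        raise GenotypeParseError(f"no variant records in {path}")
    if len(phase_seen) > 1:
        raise GenotypeValidationError("mixed '|' and '/' genotype separators in VCF")
    phased = phase_seen.pop() if phase_seen else False
    alleles = np.stack(rows, axis=1)  # (n, m, 2)
    return samples, alleles, marker_ids, phased


_CELL_CODE = {"0": 0, "1": 1, ".": MISSING}


def _read_tsv(path: str | Path):
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        raise GenotypeParseError(f"empty genotype TSV {path}")
    header = lines[0].split("\t")
    if header[0] != "individual":
        raise GenotypeParseError("genotype TSV must start with an 'individual' column")
    marker_ids = header[1:]
    ids: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    phase_seen: set[str] = set()
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(header):
            raise GenotypeParseError(f"line {lineno}: expected {len(header)} columns")
        ids.append(fields[0])
        row: list[tuple[int, int]] = []
        for cell in fields[1:]:
            sep = "|" if "|" in cell else "/" if "/" in cell else None
            if sep is None:
                raise GenotypeParseError(f"line {lineno}: malformed genotype cell {cell!r}")
            a, b = cell.split(sep)
            try:
                row.append((_CELL_CODE[a], _CELL_CODE[b]))
            except KeyError:
                raise GenotypeParseError(
                    f"line {lineno}: allele code outside 0/1/. in cell {cell!r}"
                ) from None
            if not (a == "." and b == "."):
                phase_seen.add(sep)
        rows.append(row)
    if len(phase_seen) > 1:
        raise GenotypeValidationError("mixed '|' and '/' genotype separators in TSV")
    phased = phase_seen == {"|"}
    alleles = np.array(rows, dtype=np.int8)
    return ids, alleles, marker_ids, phased


def write_genotypes(g: PhasedGenotypeMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write genotypes as TSV (default) or minimal VCF 4.2 with GT fields only."""
    if format == "tsv":
        _write_tsv(g, path)
    elif format == "vcf":
        _write_vcf(g, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _cell(a: int, b: int, sep: str) -> str:
    ca = "." if a == MISSING else str(int(a))
    cb = "." if b == MISSING else str(int(b))
    return f"{ca}{sep}{cb}"


def _write_tsv(g: PhasedGenotypeMatrix, path: str | Path) -> None:
    sep = "|" if g.phased else "/"
    with open(path, "w") as fh:
        fh.write(_TOOL_HEADER + "\n")
        fh.write("individual\t" + "\t".join(g.gmap.marker_ids) + "\n")
        for i, ind in enumerate(g.individuals):
            cells = [_cell(a, b, sep) for a, b in g.alleles[i]]
            fh.write(ind + "\t" + "\t".join(cells) + "\n")


def _write_vcf(g: PhasedGenotypeMatrix, path: str | Path) -> None:
    sep = "|" if g.phased else "/"
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write(f"##source={_TOOL_HEADER.lstrip('# ')}\n")
    for chrom in g.gmap.chromosome_names:
        buf.write(f"##contig=<ID={chrom}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(g.individuals)
        + "\n"
    )
    # VCF POS must be a positive integer; encode the cM position at a fixed
    # 1e-4 cM resolution so the map round-trips through reading code that
    # ignores POS anyway.
    for m, (mid, chrom, pos) in enumerate(
        zip(g.gmap.marker_ids, g.gmap.chromosomes, g.gmap.positions_cM)
    ):
        pos_int = int(round(pos * 10_000)) + 1
        cells = "\t".join(_cell(a, b, sep) for a, b in g.alleles[:, m, :])
        buf.write(f"{chrom}\t{pos_int}\t{mid}\tA\tT\t.\tPASS\t.\tGT\t{cells}\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# line records


def read_lines(path: str | Path, assay_length: int | None = None) -> list[LineRecord]:
    """Read inbred-line derivation records from TSV.

    Columns: line_id, population, block, generations_survived, status
    (``extinct`` or ``censored``). If ``assay_length`` is given, records are
    validated against it (censored lines must sit at the assay end).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["line_id", "population", "block", "generations_survived", "status"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GenotypeParseError(f"line-record TSV missing columns {missing}")
    records: list[LineRecord] = []
    for i, row in df.iterrows():
        try:
            gens = int(row["generations_survived"])
        except (TypeError, ValueError):
            raise GenotypeParseError(
                f"row {i + 2}: non-integer generations_survived "
                f"{row['generations_survived']!r}"
            ) from None
        records.append(
            LineRecord(
                line_id=str(row["line_id"]),
                population=str(row["population"]),
                block=str(row["block"]),
                generations_survived=gens,
                status=str(row["status"]),
                assay_length=assay_length,
            )
        )
    return records


def write_lines(records: Iterable[LineRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_TOOL_HEADER + "\n")
        fh.write("line_id\tpopulation\tblock\tgenerations_survived\tstatus\n")
        for r in records:
            fh.write(
                f"{r.line_id}\t{r.population}\t{r.block}\t"
                f"{r.generations_survived}\t{r.status}\n"
            )
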