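"""Genome coordinate frame and gene models.

Coordinates are 0-based half-open throughout the in-memory API; BED is the
on-disk interchange format. 1-based inclusive coordinates appear only in
human-readable report text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd


class InvalidParameterError(ValueError):
    """A parameter violates an operation's precondition."""


@dataclass
class GenomeDef:
    """A genome as chromosome sizes plus CpG dinucleotide positions.

    ``cpg_positions[chrom]`` is a strictly increasing int array of 0-based
    coordinates, each < the chromosome length.
    """

    chrom_names: list[str]
    chrom_lengths: list[int]
    cpg_positions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise InvalidParameterError("chrom_names and chrom_lengths differ in length")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if length <= 0:
                raise InvalidParameterError(f"chromosome {name} has non-positive length {length}")
        for name in self.cpg_positions:
            if name not in self.chrom_names:
                raise InvalidParameterError(f"CpG positions given for unknown chromosome {name}")
        for name, pos in self.cpg_positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            self.cpg_positions[name] = pos
            if pos.size:
                if np.any(np.diff(pos) <= 0):
                    raise InvalidParameterError(f"CpG positions on {name} not strictly increasing")
                if pos[0] < 0 or pos[-1] >= self.length_of(name):
                    raise InvalidParameterError(f"CpG position out of bounds on {name}")

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def cpgs(self, chrom: str) -> np.ndarray:
        return self.cpg_positions.get(chrom, np.empty(0, dtype=np.int64))

    def cpg_count(self, chrom: str, start: int, end: int) -> int:
        """Number of CpG positions in [start, end)."""
        pos = self.cpgs(chrom)
        return int(np.searchsorted(pos, end, side="left") - np.searchsorted(pos, start, side="left"))

    # ---- on-disk formats -------------------------------------------------

    def write_chrom_sizes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in zip(self.chrom_names, self.chrom_lengths):
                fh.write(f"{name}\t{length}\n")

    def write_cpg_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in self.chrom_names:
                for p in self.cpgs(name):
                    fh.write(f"{name}\t{p}\t{p + 2}\n")

    @classmethod
    def read(cls, chrom_sizes: str | Path, cpg_bed: str | Path | None = None) -> "GenomeDef":
        sizes = pd.read_csv(chrom_sizes, sep="\t", header=None, names=["chrom", "length"],
                            dtype={"chrom": str})
        cpgs: dict[str, np.ndarray] = {}
        if cpg_bed is not None:
            bed = pd.read_csv(cpg_bed, sep="\t", header=None, usecols=[0, 1],
                              names=["chrom", "start"], dtype={"chrom": str})
            for chrom, grp in bed.groupby("chrom", sort=False):
                cpgs[str(chrom)] = np.sort(grp["start"].to_numpy(np.int64))
        return cls(list(sizes["chrom"]), [int(x) for x in sizes["length"]], cpgs)


@dataclass(frozen=True)
class GeneModel:
    """One gene body: id, symbol, chrom, [start, end) span and strand."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise InvalidParameterError(f"gene {self.gene_id}: end {self.end} <= start {self.start}")
        if self.strand not in ("+", "-", "."):
            raise InvalidParameterError(f"gene {self.gene_id}: bad strand {self.strand!r}")


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};Name={g.symbol}"
            # GFF3 is 1-based inclusive
            fh.write(f"{g.chrom}\tepidmr\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n")


def _gff3_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            if k.strip() == key:
                return v.strip()
    return None


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (``gene`` features) or BED6."""
    path = Path(path)
    genes: list[GeneModel] = []
    if path.suffix.lower() in (".bed", ".bed6"):
        bed = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        for _, row in bed.iterrows():
            name = str(row[3]) if len(row) > 3 else f"gene{len(genes)}"
            strand = str(row[5]) if len(row) > 5 else "."
            genes.append(GeneModel(name, name, str(row[0]), int(row[1]), int(row[2]), strand))
        return genes
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            gid = _gff3_attr(f[8], "ID") or f"gene{len(genes)}"
            sym = _gff3_attr(f[8], "Name") or gid
            genes.append(GeneModel(gid, sym, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    return genes
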