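"""Band-matrix container and file formats for dominant-marker data.

A dominant-marker survey (ISSR, RAPD, AFLP) scores each individual at each
amplified locus as band present (1) or absent (0).  Loci are grouped by the
primer that amplified them, and individuals carry a population label.  The
:class:`BandMatrix` is the single input object for every analysis in this
package.

File dialect: individuals are rows, loci are columns, the header names each
locus ``PRIMER:index`` so the primer assignment travels with the matrix; the
population map is a separate two-column table (individual, population).
Missing scores are written ``NA`` and exported to STRUCTURE files as ``-9``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BandMatrix",
    "PrimerPanel",
    "read_band_matrix",
    "write_band_matrix",
    "read_popmap",
    "write_popmap",
    "export_structure_format",
]

MISSING_IN = "NA"
MISSING_OUT = -9


@dataclass
class PrimerPanel:
    """Optional primer metadata: sequence, annealing temperature, band size range.

    Pure bookkeeping; no computation consumes the sequences.
    """

    names: list[str]
    sequence: dict[str, str] = field(default_factory=dict)
    annealing_c: dict[str, float] = field(default_factory=dict)
    size_range_bp: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate primer names in panel")
        for name, (lo, hi) in self.size_range_bp.items():
            if lo > hi:
                raise ValueError(f"primer {name!r}: size range lower > upper")


@dataclass
class BandMatrix:
    """Individuals x loci presence/absence scores with primer and population maps.

    Parameters
    ----------
    data : ndarray of shape (n_individuals, n_loci)
        Float array with entries 0.0, 1.0 or ``nan`` (missing score).
    individual_ids, locus_ids : ordered unique labels.
    primer_of : mapping locus id -> primer name.
    population_of : mapping individual id -> population label.
    """

    data: np.ndarray
    individual_ids: list[str]
    locus_ids: list[str]
    primer_of: dict[str, str]
    population_of: dict[str, str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.individual_ids = list(self.individual_ids)
        self.locus_ids = list(self.locus_ids)
        n, L = self.data.shape if self.data.ndim == 2 else (0, 0)
        if self.data.ndim != 2 or n < 2 or L < 1:
            raise ValueError("band matrix needs >=2 individuals and >=1 locus")
        if len(self.individual_ids) != n or len(self.locus_ids) != L:
            raise ValueError("id lists do not match data shape")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.locus_ids)) != L:
            raise ValueError("duplicate locus ids")
        bad = ~(np.isnan(self.data) | (self.data == 0) | (self.data == 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"non-binary score {self.data[i, j]!r} at individual "
                f"{self.individual_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        missing_primer = [l for l in self.locus_ids if l not in self.primer_of]
        if missing_primer:
            raise ValueError(f"loci without primer assignment: {missing_primer[:5]}")
        missing_pop = [i for i in self.individual_ids if i not in self.population_of]
        if missing_pop:
            raise ValueError(f"individuals without population: {missing_pop[:5]}")

    # -- basic views -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.data.shape[0]

    @property
    def n_loci(self) -> int:
        return self.data.shape[1]

    @property
    def primers(self) -> list[str]:
        """Primer names in order of first appearance along the locus axis."""
        seen: dict[str, None] = {}
        for l in self.locus_ids:
            seen.setdefault(self.primer_of[l], None)
        return list(seen)

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance along the individual axis."""
        seen: dict[str, None] = {}
        for i in self.individual_ids:
            seen.setdefault(self.population_of[i], None)
        return list(seen)

    def loci_of_primer(self, primer: str) -> np.ndarray:
        """Column indices of the loci amplified by *primer*."""
        idx = np.array(
            [j for j, l in enumerate(self.locus_ids) if self.primer_of[l] == primer],
            dtype=int,
        )
        if idx.size == 0:
            raise KeyError(f"unknown primer {primer!r}")
        return idx

    def individuals_of_population(self, pop: str) -> np.ndarray:
        idx = np.array(
            [i for i, g in enumerate(self.individual_ids) if self.population_of[g] == pop],
            dtype=int,
        )
        if idx.size == 0:
            raise KeyError(f"unknown population {pop!r}")
        return idx

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for g in self.individual_ids:
            p = self.population_of[g]
            sizes[p] = sizes.get(p, 0) + 1
        return sizes

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"{self.primer_of[l]}:{l.split(':', 1)[-1]}" if ":" in l else l
                for l in self.locus_ids]
        return pd.DataFrame(self.data, index=self.individual_ids, columns=cols)


# -- delimited-text round trip --------------------------------------------


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column (individual, population) table; header optional."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("popmap needs two columns: individual, population")
    first = df.iloc[0]
    if str(first.iloc[0]).lower() in {"individual", "id", "sample"}:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_popmap(population_of: dict[str, str], path: str | Path) -> None:
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        for ind, pop in population_of.items():
            fh.write(f"{ind}{sep}{pop}\n")


def read_band_matrix(
    path: str | Path,
    popmap: str | Path | dict[str, str],
    missing: str = MISSING_IN,
) -> BandMatrix:
    """Read a delimited band matrix (individuals as rows, ``PRIMER:i`` columns).

    Every locus header must be ``PRIMER:index``; the primer name is the part
    before the last colon.  Cell values other than 0, 1 or *missing* are
    rejected with their coordinates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    individual_ids = [str(i) for i in df.index]
    locus_ids = [str(c) for c in df.columns]
    primer_of: dict[str, str] = {}
    for l in locus_ids:
        if ":" not in l:
            raise ValueError(f"locus {l!r} has no PRIMER:index header; cannot assign primer")
        primer_of[l] = l.rsplit(":", 1)[0]

    data = np.empty(df.shape, dtype=float)
    for i, row in enumerate(df.itertuples(index=False)):
        for j, cell in enumerate(row):
            cell = str(cell).strip()
            if cell == missing or cell.lower() == "nan":
                data[i, j] = np.nan
            elif cell in {"0", "1"}:
                data[i, j] = float(cell)
            else:
                raise ValueError(
                    f"non-binary cell {cell!r} at row {individual_ids[i]!r}, "
                    f"column {locus_ids[j]!r}"
                )
    if not isinstance(popmap, dict):
        popmap = read_popmap(popmap)
    return BandMatrix(data, individual_ids, locus_ids, primer_of, popmap)


def write_band_matrix(m: BandMatrix, path: str | Path, missing: str = MISSING_IN) -> None:
    """Write the matrix in the dialect :func:`read_band_matrix` accepts."""
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        fh.write("id" + sep + sep.join(m.locus_ids) + "\n")
        for i, ind in enumerate(m.individual_ids):
            cells = [
                missing if np.isnan(v) else str(int(v)) for v in m.data[i]
            ]
            fh.write(ind + sep + sep.join(cells) + "\n")


# -- STRUCTURE project-file export ----------------------------------------


def export_structure_format(m: BandMatrix, coding: str = "haploid") -> str:
    """Export the band matrix as a STRUCTURE project data file.

    ``haploid`` writes one row per individual with the 0/1 band phenotype as a
    single allele column per locus.  ``dominant-diploid`` writes two rows per
    individual using the conventional recessive-null coding (band present ->
    allele 1 on both rows, absent -> allele 0 on both rows); the band-absent
    phenotype is homozygous null under dominance, while the ambiguity of the
    band-present genotype is left to the RECESSIVEALLELES option of the
    consuming program.  Missing scores become -9.  The first two columns are
    the individual label and the population encoded as an integer in order of
    first appearance.
    """
    if coding not in {"haploid", "dominant-diploid"}:
        raise ValueError(f"unknown coding {coding!r}")
    pop_code = {p: k + 1 for k, p in enumerate(m.populations)}
    out = io.StringIO()
    rows_per_ind = 1 if coding == "haploid" else 2
    for i, ind in enumerate(m.individual_ids):
        cells = [
            str(MISSING_OUT) if np.isnan(v) else str(int(v)) for v in m.data[i]
        ]
        for _ in range(rows_per_ind):
            out.write(
                f"{ind}\t{pop_code[m.population_of[ind]]}\t" + "\t".join(cells) + "\n"
            )
    return out.getvalue()
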