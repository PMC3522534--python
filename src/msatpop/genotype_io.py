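"""Genepop-format genotype input/output and dataset assembly.

The central container is :class:`Dataset`: a diploid individuals x loci
allele matrix (non-negative integer allele labels, 0 = missing) together
with per-individual metadata (population, sex, season, collection date)
and per-population geographic coordinates (WGS84 decimal degrees).

Genepop dialect notes
---------------------
* the first line is a title and is ignored;
* locus names follow, either one per line or comma-separated on one line;
* population blocks are delimited by a line reading ``Pop`` (any case);
* an individual line is ``id , a1a2 b1b2 ...`` where each genotype token
  concatenates two fixed-width allele codes (2 or 3 digits per allele);
* ``00``/``000`` encodes a missing allele.  A half-missing pair is coerced
  to fully missing (logged), since every downstream statistic assumes
  complete genotype pairs.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Individual",
    "Dataset",
    "Grouping",
    "GenepopParseError",
    "read_genepop",
    "write_genepop",
    "attach_metadata",
    "pool_temporal",
    "haversine_km",
]

EARTH_RADIUS_KM = 6371.0088

SEXES = ("F", "M", "unknown")


class GenepopParseError(ValueError):
    """Raised when a Genepop file cannot be parsed."""


@dataclass
class Individual:
    id: str
    population: str
    sex: str = "unknown"
    season_label: str = ""
    collection_date: str = ""  # "YYYY-MM" when known
    source_population: str = ""  # original sample label before temporal pooling

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")


@dataclass
class Dataset:
    """Diploid multilocus genotypes plus sample metadata.

    ``genotypes`` has shape (n_individuals, n_loci, 2); allele label 0 is
    the missing-data code and a pair is either fully observed or (0, 0).
    """

    individuals: list[Individual]
    loci: list[str]
    genotypes: np.ndarray
    site_coords: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if self.genotypes.shape != (n, L, 2):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} != ({n}, {L}, 2)"
            )
        if (self.genotypes < 0).any():
            raise ValueError("allele labels must be non-negative")
        half = (self.genotypes == 0).sum(axis=2) == 1
        if half.any():
            ind, loc = np.nonzero(half)
            for i, l in zip(ind, loc):
                logger.warning(
                    "half-missing genotype coerced to missing: individual %s locus %s",
                    self.individuals[i].id, self.loci[l],
                )
            self.genotypes[half] = 0

    # -- basic accessors ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.population, None)
        return list(seen)

    def population_index(self, population: str) -> np.ndarray:
        idx = np.array(
            [i for i, ind in enumerate(self.individuals) if ind.population == population],
            dtype=np.intp,
        )
        if idx.size == 0:
            raise KeyError(f"population {population!r} not in dataset")
        return idx

    def population_genotypes(self, population: str) -> np.ndarray:
        return self.genotypes[self.population_index(population)]

    def subset(self, mask: np.ndarray) -> "Dataset":
        """Row subset by boolean mask or index array (metadata preserved)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.nonzero(mask)[0]
        else:
            idx = mask.astype(np.intp)
        inds = [replace(self.individuals[i]) for i in idx]
        return Dataset(inds, list(self.loci), self.genotypes[idx].copy(),
                       dict(self.site_coords))

    def select_sex(self, sex: str) -> "Dataset":
        mask = np.array([ind.sex == sex for ind in self.individuals])
        return self.subset(mask)

    def relabel_populations(self, mapping: dict[str, str]) -> "Dataset":
        """Merge/rename populations; coordinates carried over when consistent."""
        inds = []
        for ind in self.individuals:
            new = mapping.get(ind.population, ind.population)
            inds.append(replace(ind, population=new,
                                source_population=ind.source_population or ind.population))
        coords: dict[str, tuple[float, float]] = {}
        for pop, xy in self.site_coords.items():
            new = mapping.get(pop, pop)
            if new in coords and not np.allclose(coords[new], xy):
                coords.pop(new, None)  # merged sites at distinct places: drop
            else:
                coords[new] = xy
        return Dataset(inds, list(self.loci), self.genotypes.copy(), coords)

    def summary(self) -> dict:
        pops = self.populations
        return {
            "n_individuals": self.n_individuals,
            "n_loci": self.n_loci,
            "loci": list(self.loci),
            "populations": {p: int(self.population_index(p).size) for p in pops},
            "has_coordinates": sorted(self.site_coords),
        }


@dataclass
class Grouping:
    """Assignment of each population to one label of a higher level.

    e.g. genetic cluster membership, region membership, island/mainland.
    """

    name: str
    assignment: dict[str, str]

    def validate(self, ds: Dataset) -> None:
        missing = [p for p in ds.populations if p not in self.assignment]
        if missing:
            raise ValueError(
                f"grouping {self.name!r} missing populations: {missing}"
            )

    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.assignment.values():
            seen.setdefault(v, None)
        return list(seen)

    def members(self, label: str) -> list[str]:
        return [p for p, g in self.assignment.items() if g == label]


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in km between two WGS84 (lon, lat) points."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


# ---------------------------------------------------------------------------
# Genepop parsing / writing
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _detect_width(tokens: list[tuple[int, str]]) -> int:
    lengths = {len(t) for _, t in tokens}
    if lengths <= {4}:
        return 2
    if lengths <= {6}:
        return 3
    bad = next(((ln, t) for ln, t in tokens if len(t) not in (4, 6)),
               tokens[0])
    raise GenepopParseError(
        f"line {bad[0]}: genotype token {bad[1]!r} has unsupported width "
        f"(file mixes widths {sorted(lengths)})"
    )


def read_genepop(path, digit_width: str | int = "auto",
                 pop_names: str | list[str] = "first") -> Dataset:
    """Parse a Genepop file into a :class:`Dataset`.

    Parameters
    ----------
    digit_width:
        ``"auto"`` (detected per file), 2 or 3 digits per allele.
    pop_names:
        ``"first"``/``"last"`` name each block after its first/last
        individual id; ``"sequential"`` uses pop1, pop2, ...; or give an
        explicit list of names, one per block.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenepopParseError("empty file")

    # locus header: everything between the title and the first Pop line
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        for name in lines[i].split(","):
            name = name.strip()
            if name:
                loci.append(name)
        i += 1
    if i == len(lines):
        raise GenepopParseError("no 'Pop' line found")
    if not loci:
        raise GenepopParseError("no locus names before first 'Pop'")

    blocks: list[list[tuple[int, str, list[str]]]] = []
    current: list[tuple[int, str, list[str]]] | None = None
    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if _POP_RE.match(line):
            current = []
            blocks.append(current)
            continue
        if not line.strip():
            continue
        if current is None:
            raise GenepopParseError(f"line {lineno + 1}: data before first 'Pop'")
        if "," not in line:
            raise GenepopParseError(f"line {lineno + 1}: missing ',' separator")
        ident, rest = line.split(",", 1)
        toks = rest.split()
        if len(toks) != len(loci):
            raise GenepopParseError(
                f"line {lineno + 1}: expected {len(loci)} genotypes, got {len(toks)}"
            )
        current.append((lineno + 1, ident.strip(), toks))

    if any(len(b) == 0 for b in blocks):
        raise GenepopParseError("empty population block")

    all_tokens = [(ln, t) for b in blocks for ln, _, toks in b for t in toks]
    for ln, t in all_tokens:
        if not t.isdigit():
            raise GenepopParseError(f"line {ln}: non-numeric genotype token {t!r}")
    if digit_width == "auto":
        width = _detect_width(all_tokens)
    else:
        width = int(digit_width)
        for ln, t in all_tokens:
            if len(t) != 2 * width:
                raise GenepopParseError(
                    f"line {ln}: token {t!r} not {2 * width} digits wide"
                )

    individuals: list[Individual] = []
    rows: list[list[tuple[int, int]]] = []
    names: list[str] = []
    for bi, block in enumerate(blocks):
        if isinstance(pop_names, str):
            if pop_names == "first":
                name = block[0][1]
            elif pop_names == "last":
                name = block[-1][1]
            elif pop_names == "sequential":
                name = f"pop{bi + 1}"
            else:
                raise ValueError(f"unknown pop_names mode {pop_names!r}")
        else:
            if len(pop_names) != len(blocks):
                raise ValueError("pop_names list length != number of blocks")
            name = pop_names[bi]
        names.append(name)
        for _, ident, toks in block:
            individuals.append(Individual(id=ident, population=name))
            rows.append([(int(t[:width]), int(t[width:])) for t in toks])

    geno = np.array(rows, dtype=np.int64)
    return Dataset(individuals, loci, geno)


def write_genepop(ds: Dataset, path, digit_width: int = 3,
                  title: str = "msatpop export") -> None:
    """Write a :class:`Dataset` in canonical Genepop format."""
    limit = 10 ** digit_width
    if (ds.genotypes >= limit).any():
        raise ValueError(f"allele label too wide for {digit_width}-digit coding")
    pops = ds.populations
    for p in pops:
        if ds.population_index(p).size == 0:  # pragma: no cover - defensive
            raise ValueError(f"empty population block {p!r}")
    if ds.n_individuals == 0:
        raise ValueError("cannot write empty dataset (Genepop forbids empty blocks)")
    fmt = f"0{digit_width}d"
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in ds.loci:
            fh.write(locus + "\n")
        for pop in pops:
            fh.write("Pop\n")
            for i in ds.population_index(pop):
                toks = " ".join(
                    format(a, fmt) + format(b, fmt) for a, b in ds.genotypes[i]
                )
                fh.write(f"{ds.individuals[i].id} , {toks}\n")


# ---------------------------------------------------------------------------
# Metadata and temporal pooling
# ---------------------------------------------------------------------------

_META_COLS = ("id", "population", "longitude", "latitude", "sex", "season", "date")


def attach_metadata(ds: Dataset, table) -> Dataset:
    """Join a per-individual metadata table onto a dataset.

    ``table`` is a pandas DataFrame or a CSV path with columns
    id, population, longitude, latitude, sex, season, date.  Coordinates
    propagate to ``site_coords``; ids present in the table but not the
    dataset produce a warning, and conflicting coordinates for one
    population are an error.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, dtype={"id": str})
    missing_cols = [c for c in _META_COLS if c not in table.columns]
    if missing_cols:
        raise ValueError(f"metadata table missing columns: {missing_cols}")
    if table["id"].duplicated().any():
        dups = table.loc[table["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate metadata rows for ids: {dups}")

    meta = table.set_index("id")
    coords: dict[str, tuple[float, float]] = {}
    for pop, sub in table.groupby("population"):
        lon, lat = sub["longitude"].astype(float), sub["latitude"].astype(float)
        if lon.nunique() > 1 or lat.nunique() > 1:
            raise ValueError(f"conflicting coordinates for population {pop!r}")
        coords[str(pop)] = (float(lon.iloc[0]), float(lat.iloc[0]))

    ds_ids = {ind.id for ind in ds.individuals}
    orphans = sorted(set(meta.index) - ds_ids)
    if orphans:
        logger.warning("metadata ids not in dataset: %s", orphans)
    unmatched = sorted(ds_ids - set(meta.index))
    if unmatched:
        logger.warning("dataset ids without metadata: %s", unmatched)

    individuals = []
    for ind in ds.individuals:
        if ind.id in meta.index:
            row = meta.loc[ind.id]
            sex = str(row["sex"]) if pd.notna(row["sex"]) else "unknown"
            if sex not in SEXES:
                sex = "unknown"
            individuals.append(replace(
                ind,
                population=str(row["population"]),
                sex=sex,
                season_label=str(row["season"]) if pd.notna(row["season"]) else "",
                collection_date=str(row["date"]) if pd.notna(row["date"]) else "",
            ))
        else:
            individuals.append(replace(ind))
    new_coords = dict(ds.site_coords)
    new_coords.update(coords)
    return Dataset(individuals, list(ds.loci), ds.genotypes.copy(), new_coords)


def pool_temporal(ds: Dataset, pools: dict[str, list[str]]) -> Dataset:
    """Concatenate seasonal samples under one population label.

    ``pools`` maps the pooled label to the list of existing population
    (seasonal sample) labels to merge.  Provenance is retained in each
    individual's ``source_population``.  Intended for samples already
    shown temporally homogeneous (no significant exact differentiation).
    """
    present = set(ds.populations)
    mapping: dict[str, str] = {}
    for new, parts in pools.items():
        absent = [p for p in parts if p not in present]
        if absent:
            raise ValueError(f"pooling labels not in dataset: {absent}")
        for p in parts:
            mapping[p] = new
    return ds.relabel_populations(mapping)


def parse_year_month(date: str) -> tuple[int, int]:
    """Parse 'YYYY-MM' (also accepts 'Mon, YYYY' style month names)."""
    m = re.match(r"^(\d{4})-(\d{1,2})$", date.strip())
    if m:
        return int(m.group(1)), int(m.group(2))
    months = {
        "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
        "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
    }
    m = re.match(r"^([A-Za-z]+)\.?,?\s+(\d{4})$", date.strip())
    if m and m.group(1)[:3].lower() in months:
        return int(m.group(2)), months[m.group(1)[:3].lower()]
    raise ValueError(f"cannot parse collection date {date!r}")
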