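"""Genotype data model and text-format I/O for co-dominant microsatellite panels.

Alleles are stored as integer fragment sizes in base pairs (the raw output of
fragment analysis), never as opaque codes: size-based statistics such as the
Garza-Williamson M-ratio need true sizes.  GenePop's 3-digit numeric-code
constraint is bridged with a JSON sidecar mapping codes back to sizes.

A genotype cell is either a complete unordered pair of allele sizes or missing
entirely; half-calls are rejected at parse time.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

SEASONS = ("rainy", "dry", "unknown")


class PanelFormatError(ValueError):
    """Raised when a genotype file cannot be parsed under the named dialect."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus: name, repeat-unit length (bp) and observed allele sizes."""

    name: str
    motif_length: int | None = None
    allele_register: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.motif_length is not None and self.motif_length < 1:
            raise ValueError(f"motif_length must be >= 1, got {self.motif_length}")
        reg = tuple(sorted(int(a) for a in self.allele_register))
        if any(a <= 0 for a in reg):
            raise ValueError(f"allele sizes must be positive integers: {reg}")
        object.__setattr__(self, "allele_register", reg)


@dataclass(frozen=True)
class Individual:
    """Sampled fish: id plus river section, season, capture year and optional stock."""

    id: str
    section: str = "unknown"
    season: str = "unknown"
    year: int | None = None
    stock: str | None = None

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}, got {self.season!r}")


class GenotypePanel:
    """Individuals x loci diploid allele-size matrix with sample metadata.

    ``calls`` has shape (n_individuals, n_loci, 2); missing cells are
    ``(-1, -1)`` and each non-missing pair is canonicalized smaller-first.
    """

    def __init__(
        self,
        loci: Sequence[Locus],
        individuals: Sequence[Individual],
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int32)
        if calls.shape != (len(individuals), len(loci), 2):
            raise ValueError(
                f"calls shape {calls.shape} != ({len(individuals)}, {len(loci)}, 2)"
            )
        ids = [ind.id for ind in individuals]
        if len(set(ids)) != len(ids):
            raise ValueError("individual ids must be unique within a panel")
        # half-calls are invalid: a cell is missing entirely or complete
        half = (calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise ValueError(f"half-called genotype at individual {ids[i]}, locus {loci[j].name}")
        calls = np.sort(calls, axis=2)  # canonical order, missing (-1,-1) unaffected
        # rebuild registers from observed data, preserving declared alleles
        rebuilt = []
        for j, loc in enumerate(loci):
            observed = calls[:, j, :]
            observed = observed[observed != MISSING]
            register = tuple(sorted(set(loc.allele_register) | set(int(a) for a in observed)))
            if any(a <= 0 for a in register):
                raise ValueError(f"non-positive allele size at locus {loc.name}")
            rebuilt.append(replace(loc, allele_register=register))
        self.loci: tuple[Locus, ...] = tuple(rebuilt)
        self.individuals: tuple[Individual, ...] = tuple(individuals)
        self.calls = calls
        # alleles masked for Ne estimation only (set by filter_panel)
        self.ne_masked_alleles: dict[str, frozenset[int]] = {}

    # ------------------------------------------------------------------ basics
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, name: str) -> int:
        for j, loc in enumerate(self.loci):
            if loc.name == name:
                return j
        raise KeyError(f"no locus named {name!r}")

    def locus(self, name: str) -> Locus:
        return self.loci[self.locus_index(name)]

    def genotypes(self, locus: str, indices: np.ndarray | None = None) -> np.ndarray:
        """Non-missing genotype pairs (m, 2) at a locus, optionally restricted to rows."""
        j = self.locus_index(locus)
        g = self.calls[:, j, :] if indices is None else self.calls[indices, j, :]
        return g[g[:, 0] != MISSING]

    def group_indices(self, by: str = "section") -> dict[str, np.ndarray]:
        """Row indices per population label for a grouping variable.

        ``by`` is one of section/season/stock/year, or "all" for a single pool.
        Individuals with an unknown/absent label are dropped from the grouping.
        """
        if by == "all":
            return {"all": np.arange(self.n_individuals)}
        groups: dict[str, list[int]] = {}
        for i, ind in enumerate(self.individuals):
            label = getattr(ind, by)
            if label in (None, "unknown"):
                continue
            groups.setdefault(str(label), []).append(i)
        return {k: np.asarray(v, dtype=np.intp) for k, v in sorted(groups.items())}

    def subset(self, indices: Iterable[int] | None = None, loci: Iterable[str] | None = None) -> "GenotypePanel":
        idx = np.arange(self.n_individuals) if indices is None else np.asarray(list(indices), dtype=np.intp)
        names = [loc.name for loc in self.loci] if loci is None else list(loci)
        jj = [self.locus_index(n) for n in names]
        out = GenotypePanel(
            [Locus(self.loci[j].name, self.loci[j].motif_length) for j in jj],
            [self.individuals[i] for i in idx],
            self.calls[np.ix_(idx, jj)],
        )
        out.ne_masked_alleles = {n: v for n, v in self.ne_masked_alleles.items() if n in names}
        return out

    def with_stocks(self, stocks: Sequence[str | None]) -> "GenotypePanel":
        """Return a copy with per-individual stock labels replaced."""
        if len(stocks) != self.n_individuals:
            raise ValueError("one stock label per individual required")
        inds = [replace(ind, stock=s) for ind, s in zip(self.individuals, stocks)]
        out = GenotypePanel(self.loci, inds, self.calls)
        out.ne_masked_alleles = dict(self.ne_masked_alleles)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        return (
            self.loci == other.loci
            and self.individuals == other.individuals
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return f"GenotypePanel({self.n_individuals} individuals x {self.n_loci} loci)"


# ---------------------------------------------------------------------- filter
def filter_panel(
    panel: GenotypePanel,
    min_maf: float = 0.0,
    drop_loci: Iterable[str] = (),
    drop_missing_above: float = 1.0,
) -> GenotypePanel:
    """QC filter: drop loci, mask rare alleles for Ne estimation, drop gappy loci.

    Alleles below ``min_maf`` are *masked* (recorded in ``ne_masked_alleles``,
    consulted by the LD-Ne estimator) rather than deleted: diversity statistics
    keep seeing them.  ``drop_missing_above`` removes loci whose missing-data
    fraction exceeds the threshold.
    """
    if not 0.0 <= min_maf <= 1.0 or not 0.0 <= drop_missing_above <= 1.0:
        raise ValueError("thresholds must be in [0, 1]")
    drop = set(drop_loci)
    unknown = drop - {loc.name for loc in panel.loci}
    if unknown:
        raise KeyError(f"cannot drop unknown loci: {sorted(unknown)}")
    keep = []
    for j, loc in enumerate(panel.loci):
        if loc.name in drop:
            continue
        missing_frac = float((panel.calls[:, j, 0] == MISSING).mean())
        if missing_frac > drop_missing_above:
            continue
        keep.append(loc.name)
    if not keep:
        raise ValueError("filter would drop all loci")
    out = panel.subset(loci=keep)
    if min_maf > 0:
        masked: dict[str, frozenset[int]] = {}
        for loc in out.loci:
            g = out.genotypes(loc.name)
            if g.size == 0:
                continue
            alleles, counts = np.unique(g, return_counts=True)
            freqs = counts / counts.sum()
            rare = frozenset(int(a) for a, f in zip(alleles, freqs) if f < min_maf)
            if rare:
                masked[loc.name] = rare
        out.ne_masked_alleles = masked
    return out


# ---------------------------------------------------------------- tabular I/O
_META_COLS = ("id", "section", "season", "year", "stock")


def _write_tabular(panel: GenotypePanel, path: Path) -> None:
    rows = []
    for i, ind in enumerate(panel.individuals):
        row: dict[str, object] = {
            "id": ind.id,
            "section": ind.section,
            "season": ind.season,
            "year": "" if ind.year is None else ind.year,
            "stock": "" if ind.stock is None else ind.stock,
        }
        for j, loc in enumerate(panel.loci):
            a, b = panel.calls[i, j]
            row[f"{loc.name}_1"] = "" if a == MISSING else int(a)
            row[f"{loc.name}_2"] = "" if b == MISSING else int(b)
        rows.append(row)
    df = pd.DataFrame(rows)
    motifs = ",".join(
        f"{loc.name}={loc.motif_length}" for loc in panel.loci if loc.motif_length is not None
    )
    with open(path, "w", encoding="utf-8") as fh:
        if motifs:
            fh.write(f"# motif: {motifs}\n")
        df.to_csv(fh, index=False)


def _read_tabular(path: Path) -> GenotypePanel:
    motifs: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        header_lines = 0
        if first.startswith("#"):
            header_lines = 1
            m = re.match(r"#\s*motif:\s*(.*)", first.strip())
            if m and m.group(1):
                for part in m.group(1).split(","):
                    name, _, val = part.partition("=")
                    motifs[name.strip()] = int(val)
    try:
        df = pd.read_csv(path, skiprows=header_lines, sep=None, engine="python", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise PanelFormatError(f"cannot parse tabular file {path}: {exc}") from exc
    if "id" not in df.columns:
        raise PanelFormatError(f"{path}: tabular file needs an 'id' column")
    locus_names: list[str] = []
    for col in df.columns:
        if col.endswith("_1") and col not in _META_COLS:
            base = col[:-2]
            if f"{base}_2" not in df.columns:
                raise PanelFormatError(f"{path}: locus {base} has column {col} but no {base}_2")
            locus_names.append(base)
    if not locus_names:
        raise PanelFormatError(f"{path}: no locus columns found")
    individuals, calls = [], []
    for ln, row in enumerate(df.itertuples(index=False), start=2 + header_lines):
        d = row._asdict()
        year_raw = d.get("year")
        year = None
        if year_raw not in (None, "") and not pd.isna(year_raw):
            year = int(float(year_raw))
        stock = d.get("stock")
        stock = None if stock in (None, "") or pd.isna(stock) else str(stock)
        season = d.get("season")
        season = "unknown" if season in (None, "") or pd.isna(season) else str(season)
        section = d.get("section")
        section = "unknown" if section in (None, "") or pd.isna(section) else str(section)
        individuals.append(Individual(str(d["id"]), section, season, year, stock))
        g = []
        for name in locus_names:
            pair = []
            for suffix in ("_1", "_2"):
                v = d[f"{name}{suffix}"]
                if v in (None, "", "NA") or pd.isna(v):
                    pair.append(MISSING)
                else:
                    try:
                        pair.append(int(float(v)))
                    except ValueError as exc:
                        raise PanelFormatError(f"{path}:{ln}: bad allele {v!r} at {name}") from exc
            g.append(pair)
        calls.append(g)
    loci = [Locus(n, motifs.get(n)) for n in locus_names]
    try:
        return GenotypePanel(loci, individuals, np.asarray(calls))
    except ValueError as exc:
        raise PanelFormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------- GenePop I/O
def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".sidecar.json")


def _write_genepop(panel: GenotypePanel, path: Path) -> None:
    if panel.n_individuals == 0 or panel.n_loci == 0:
        raise ValueError("refusing to write an empty panel")
    code_maps = {}
    for loc in panel.loci:
        if len(loc.allele_register) > 999:
            raise ValueError(f"locus {loc.name}: >999 alleles unsupported for GenePop export")
        code_maps[loc.name] = {size: rank + 1 for rank, size in enumerate(loc.allele_register)}
    groups = panel.group_indices("section") or {"all": np.arange(panel.n_individuals)}
    lines = ["msatpop GenePop export"]
    lines += [loc.name for loc in panel.loci]
    for label, idx in groups.items():
        lines.append("Pop")
        for i in idx:
            codes = []
            for j, loc in enumerate(panel.loci):
                a, b = panel.calls[i, j]
                if a == MISSING:
                    codes.append("000000")
                else:
                    cm = code_maps[loc.name]
                    codes.append(f"{cm[int(a)]:03d}{cm[int(b)]:03d}")
            lines.append(f"{panel.individuals[i].id} , " + " ".join(codes))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    sidecar = {
        "loci": {
            loc.name: {
                "motif_length": loc.motif_length,
                "codes": {str(code): size for size, code in code_maps[loc.name].items()},
            }
            for loc in panel.loci
        },
        "individuals": [
            {"id": ind.id, "section": ind.section, "season": ind.season,
             "year": ind.year, "stock": ind.stock}
            for ind in panel.individuals
        ],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1), encoding="utf-8")


def _read_genepop(path: Path) -> GenotypePanel:
    text = path.read_text(encoding="utf-8").splitlines()
    if len(text) < 3:
        raise PanelFormatError(f"{path}: truncated GenePop file")
    sidecar: dict | None = None
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text(encoding="utf-8"))
    locus_names: list[str] = []
    i = 1
    while i < len(text) and text[i].strip().lower() != "pop":
        line = text[i].strip()
        if line:
            # locus names may also come comma-separated on one line
            locus_names.extend(n.strip() for n in line.split(",") if n.strip())
        i += 1
    if not locus_names or i == len(text):
        raise PanelFormatError(f"{path}: no loci or no Pop separator found")
    meta_by_id = {}
    if sidecar:
        meta_by_id = {m["id"]: m for m in sidecar["individuals"]}
    individuals, calls = [], []
    pop_counter = 0
    for ln in range(i, len(text)):
        line = text[ln].strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_counter += 1
            continue
        if "," not in line:
            raise PanelFormatError(f"{path}:{ln + 1}: expected 'id , codes' line")
        ident, _, rest = line.partition(",")
        ident = ident.strip()
        codes = rest.split()
        if len(codes) != len(locus_names):
            raise PanelFormatError(
                f"{path}:{ln + 1}: {len(codes)} genotype codes for {len(locus_names)} loci"
            )
        g = []
        for name, code in zip(locus_names, codes):
            if not code.isdigit() or len(code) not in (4, 6):
                raise PanelFormatError(f"{path}:{ln + 1}: bad GenePop code {code!r}")
            half = len(code) // 2
            ca, cb = int(code[:half]), int(code[half:])
            if ca == 0 or cb == 0:
                if ca != cb:
                    raise PanelFormatError(f"{path}:{ln + 1}: half-missing code {code!r}")
                g.append([MISSING, MISSING])
            elif sidecar:
                table = sidecar["loci"][name]["codes"]
                g.append([int(table[str(ca)]), int(table[str(cb)])])
            else:
                g.append([ca, cb])  # foreign file: codes taken as sizes
        if ident in meta_by_id:
            m = meta_by_id[ident]
            individuals.append(Individual(ident, m["section"], m["season"], m["year"], m["stock"]))
        else:
            individuals.append(Individual(ident, section=f"pop{pop_counter}"))
        calls.append(g)
    loci = []
    for name in locus_names:
        motif = sidecar["loci"][name]["motif_length"] if sidecar else None
        loci.append(Locus(name, motif))
    calls_arr = np.asarray(calls)
    if sidecar:
        # restore the panel's original row order ("Pop" blocks reorder it)
        order = {m["id"]: k for k, m in enumerate(sidecar["individuals"])}
        if set(order) == {ind.id for ind in individuals}:
            perm = np.argsort([order[ind.id] for ind in individuals], kind="stable")
            individuals = [individuals[i] for i in perm]
            calls_arr = calls_arr[perm]
    try:
        return GenotypePanel(loci, individuals, calls_arr)
    except ValueError as exc:
        raise PanelFormatError(f"{path}: {exc}") from exc


# -------------------------------------------------------------- STRUCTURE I/O
def _write_structure(panel: GenotypePanel, path: Path, rows_per_individual: int = 2) -> None:
    if panel.n_individuals == 0 or panel.n_loci == 0:
        raise ValueError("refusing to write an empty panel")
    if rows_per_individual not in (1, 2):
        raise ValueError("rows_per_individual must be 1 or 2")
    sections = sorted({ind.section for ind in panel.individuals})
    pop_code = {s: k + 1 for k, s in enumerate(sections)}
    lines = [" ".join(loc.name for loc in panel.loci)]
    for i, ind in enumerate(panel.individuals):
        if rows_per_individual == 2:
            for copy in (0, 1):
                vals = [str(int(panel.calls[i, j, copy])) if panel.calls[i, j, copy] != MISSING else "-9"
                        for j in range(panel.n_loci)]
                lines.append(f"{ind.id} {pop_code[ind.section]} " + " ".join(vals))
        else:
            vals = []
            for j in range(panel.n_loci):
                a, b = panel.calls[i, j]
                vals += ["-9", "-9"] if a == MISSING else [str(int(a)), str(int(b))]
            lines.append(f"{ind.id} {pop_code[ind.section]} " + " ".join(vals))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_structure(path: Path) -> GenotypePanel:
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if len(lines) < 2:
        raise PanelFormatError(f"{path}: truncated STRUCTURE file")
    locus_names = lines[0].split()
    L = len(locus_names)
    body = [ln.split() for ln in lines[1:]]
    widths = {len(row) for row in body}
    if widths == {2 + L} and len(body) >= 2 and body[0][0] == body[1][0]:
        two_row = True
    elif widths == {2 + 2 * L}:
        two_row = False
    elif widths == {2 + L}:
        raise PanelFormatError(f"{path}: one allele per locus but ids not duplicated (half-calls?)")
    else:
        raise PanelFormatError(f"{path}: inconsistent column counts {sorted(widths)}")
    individuals, calls = [], []
    if two_row:
        if len(body) % 2:
            raise PanelFormatError(f"{path}: odd number of rows in two-row format")
        for r in range(0, len(body), 2):
            top, bot = body[r], body[r + 1]
            if top[0] != bot[0]:
                raise PanelFormatError(f"{path}: rows {r + 2}/{r + 3} ids differ: {top[0]} vs {bot[0]}")
            individuals.append(Individual(top[0], section=top[1]))
            g = []
            for j in range(L):
                a, b = int(top[2 + j]), int(bot[2 + j])
                if (a == -9) != (b == -9):
                    raise PanelFormatError(f"{path}: half-missing genotype for {top[0]} at {locus_names[j]}")
                g.append([MISSING, MISSING] if a == -9 else [a, b])
            calls.append(g)
    else:
        for row in body:
            individuals.append(Individual(row[0], section=row[1]))
            g = []
            for j in range(L):
                a, b = int(row[2 + 2 * j]), int(row[3 + 2 * j])
                if (a == -9) != (b == -9):
                    raise PanelFormatError(f"{path}: half-missing genotype for {row[0]}")
                g.append([MISSING, MISSING] if a == -9 else [a, b])
            calls.append(g)
    try:
        return GenotypePanel([Locus(n) for n in locus_names], individuals, np.asarray(calls))
    except ValueError as exc:
        raise PanelFormatError(f"{path}: {exc}") from exc


# ----------------------------------------------------------------- dispatchers
_READERS = {"tabular": _read_tabular, "genepop": _read_genepop, "structure": _read_structure}


def read_panel(path: str | Path, format: str = "tabular") -> GenotypePanel:
    """Read a genotype panel from one of the supported text dialects."""
    path = Path(path)
    if format not in _READERS:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(_READERS)}")
    if not path.exists():
        raise FileNotFoundError(path)
    return _READERS[format](path)


def write_panel(panel: GenotypePanel, path: str | Path, format: str = "tabular", **kwargs) -> Path:
    """Write a panel; GenePop export also writes a JSON sidecar with sizes/metadata."""
    path = Path(path)
    if panel.n_individuals == 0 or panel.n_loci == 0:
        raise ValueError("refusing to write an empty panel")
    if format == "tabular":
        _write_tabular(panel, path)
    elif format == "genepop":
        _write_genepop(panel, path)
    elif format == "structure":
        _write_structure(panel, path, **kwargs)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
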