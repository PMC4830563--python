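"""The per-species mutation-table dialect and its summary statistics.

One row per species, one column per exon (e1..eN); each cell is a
comma-separated sequence of mutation codes (blank = no mutation in that
exon). ``gd`` in every cell marks a whole-gene deletion. The packaged
fixture ``data/bird_moxd2_mutations.tsv`` is a transcription of a published
comparative survey of the MOXD2 gene across 57 bird genomes, with the 19
species reported mutation-free included as empty rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .mutation_caller import parse_code

POINT_KINDS = {"sa", "sd", "ns", "i", "d", "5d", "3d"}


class TableError(ValueError):
    pass


@dataclass(frozen=True)
class SpeciesReport:
    """Per-species per-exon code sets plus overall gene status.

    ``mutation_keys`` identify mutations for cross-species sharing tests:
    fine keys are (exon, kind, length, position); rows parsed from a table
    (which omits positions) fall back to coarse (exon, code) keys and carry
    the ``coarse_keys`` flag.
    """

    species_id: str
    cells: tuple[tuple[str, ...], ...]
    status: str
    mutation_keys: frozenset = frozenset()
    coarse_keys: bool = True
    notes: tuple[str, ...] = ()

    @property
    def n_exons(self) -> int:
        return len(self.cells)

    def cell_text(self, exon_index: int) -> str:
        return ", ".join(self.cells[exon_index - 1])

    def all_codes(self) -> list[tuple[int, str]]:
        return [
            (e, code)
            for e, cell in enumerate(self.cells, start=1)
            for code in cell
        ]

    def keys(self) -> frozenset:
        if self.mutation_keys:
            return self.mutation_keys
        return frozenset((e, code) for e, code in self.all_codes() if code != "gd")


@dataclass
class MutationTable:
    species: list[str]
    n_exons: int
    cells: dict[str, tuple[tuple[str, ...], ...]]
    numbers: dict[str, int] = field(default_factory=dict)

    def reports(self) -> list[SpeciesReport]:
        out = []
        for sp in self.species:
            cells = self.cells[sp]
            codes = [c for cell in cells for c in cell]
            if codes and all(c == "gd" for c in codes) and all(cell for cell in cells):
                status = "gene_deleted"
            elif codes:
                status = "disrupted"
            else:
                status = "intact"
            out.append(
                SpeciesReport(
                    species_id=sp, cells=cells, status=status, coarse_keys=True
                )
            )
        return out


def _parse_cell(cell: str, species: str, column: str) -> tuple[str, ...]:
    cell = cell.strip()
    if not cell:
        return ()
    codes = []
    for token in cell.split(","):
        token = token.strip()
        try:
            parse_code(token)
        except ValueError as exc:
            raise TableError(
                f"unknown code {token!r} in row {species!r}, column {column}"
            ) from exc
        codes.append(token)
    return tuple(codes)


def parse_table(tsv_path) -> MutationTable:
    """Parse a mutation table TSV. The header must name exon columns
    e1..eN; optional leading columns ``no`` and ``species`` are honoured."""
    try:
        df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise TableError(f"empty table file {tsv_path}") from exc
    exon_cols = [c for c in df.columns if c.startswith("e") and c[1:].isdigit()]
    if not exon_cols:
        raise TableError("no exon columns (e1..eN) in header")
    exon_cols.sort(key=lambda c: int(c[1:]))
    if [int(c[1:]) for c in exon_cols] != list(range(1, len(exon_cols) + 1)):
        raise TableError("exon columns must be contiguous e1..eN")
    if "species" not in df.columns:
        raise TableError("missing 'species' column")
    species: list[str] = []
    cells: dict[str, tuple[tuple[str, ...], ...]] = {}
    numbers: dict[str, int] = {}
    for _, row in df.iterrows():
        sp = row["species"].strip()
        if not sp:
            raise TableError("blank species name")
        if sp in cells:
            raise TableError(f"duplicate species {sp!r}")
        species.append(sp)
        cells[sp] = tuple(_parse_cell(row[c], sp, c) for c in exon_cols)
        if "no" in df.columns and str(row["no"]).strip().isdigit():
            numbers[sp] = int(row["no"])
    return MutationTable(
        species=species, n_exons=len(exon_cols), cells=cells, numbers=numbers
    )


def load_bird_survey() -> MutationTable:
    """The packaged 57-species bird MOXD2 mutation table."""
    ref = resources.files("pseudoscan").joinpath("data/bird_moxd2_mutations.tsv")
    with resources.as_file(ref) as path:
        return parse_table(path)


def _is_gd(cells: Iterable[tuple[str, ...]]) -> bool:
    cells = list(cells)
    return bool(cells) and all(cell == ("gd",) for cell in cells)


def summarize(table: MutationTable) -> dict[str, int]:
    """Category counts over the table.

    intact: all cells empty. gd: gd in every cell. ed_species: >=1 ed (not
    gd). point codes are sa/sd/ns/i#/d#/5d#/3d# (tl is positional evidence,
    not a point mutation). both/point_only/ed_only partition the non-gd
    mutated species; any_loss = mutated + gd.
    """
    counts = dict(
        intact=0, mutated=0, both_point_and_ed=0, point_only=0, ed_only=0,
        gd=0, ed_species=0, tl_species=0, point_species=0, any_loss=0,
    )
    for sp in table.species:
        cells = table.cells[sp]
        codes = [c for cell in cells for c in cell]
        if not codes:
            counts["intact"] += 1
            continue
        if _is_gd(cells):
            counts["gd"] += 1
            counts["any_loss"] += 1
            continue
        counts["mutated"] += 1
        counts["any_loss"] += 1
        kinds = {parse_code(c)[0] for c in codes}
        has_ed = "ed" in kinds
        has_point = bool(kinds & POINT_KINDS)
        if "tl" in kinds:
            counts["tl_species"] += 1
        if has_ed:
            counts["ed_species"] += 1
        if has_point:
            counts["point_species"] += 1
        if has_ed and has_point:
            counts["both_point_and_ed"] += 1
        elif has_point:
            counts["point_only"] += 1
        elif has_ed:
            counts["ed_only"] += 1
    return counts


def emit_table(reports: list[SpeciesReport], path: Optional[Path] = None) -> str:
    """Byte-stable TSV of species reports (sorted by species id; codes in
    canonical cell order as produced by the callers)."""
    if not reports:
        raise TableError("no reports to emit")
    n = reports[0].n_exons
    header = ["species"] + [f"e{i}" for i in range(1, n + 1)] + ["status"]
    lines = ["\t".join(header)]
    for rep in sorted(reports, key=lambda r: r.species_id):
        row = [rep.species_id] + [rep.cell_text(e) for e in range(1, n + 1)]
        row.append(rep.status)
        lines.append("\t".join(row))
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text
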