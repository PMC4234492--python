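"""Pairing and scoring of control vs. experimental replicate sets.

Raw area files carry (base name, set, plate) metadata.  This module
discovers complete replicate sets in a folder, normalizes each plate
independently, aligns control and experimental plates position by
position, attaches gene identities from an array key file, and writes
scored tables either per position or aggregated per ORF.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from colonyarray import colony_quant, normalization

__all__ = [
    "ArrayKey",
    "ScoredSet",
    "load_key_file",
    "load_feature_table",
    "discover_sets",
    "pair_and_score",
    "write_scored",
    "read_scored",
]

SCORED_COLUMNS = ["plate", "row", "col", "orf", "gene",
                  "ctrl", "ctrl_sd", "exp", "exp_sd"]


@dataclass
class ArrayKey:
    """Map from (plate, row, col) to (systematic ORF, standard gene name)."""

    entries: dict[tuple[int, int, int], tuple[str, str | None]]

    def orf(self, plate: int, row: int, col: int) -> str | None:
        entry = self.entries.get((plate, row, col))
        return entry[0] if entry else None

    def gene(self, plate: int, row: int, col: int) -> str | None:
        entry = self.entries.get((plate, row, col))
        return entry[1] if entry else None

    def backfill_genes(self, features: dict[str, str]) -> None:
        """Fill absent standard gene names from a feature table mapping
        systematic name -> standard name."""
        for pos, (orf, gene) in self.entries.items():
            if gene is None and orf in features:
                self.entries[pos] = (orf, features[orf])


def load_key_file(path: str | Path,
                  features: dict[str, str] | None = None) -> ArrayKey:
    """Load a tab-delimited array key file.

    Four or five columns per row: plate, row, column, systematic ORF
    name, and optionally the standard gene name.  Gene names absent
    from 4-column rows can be back-filled from an SGD-style feature
    table.
    """
    entries: dict[tuple[int, int, int], tuple[str, str | None]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (4, 5):
                raise ValueError(
                    f"{path}:{lineno}: expected 4 or 5 columns, got {len(parts)}")
            try:
                plate, row, col = int(parts[0]), int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer plate/row/col") from None
            if min(plate, row, col) < 1:
                raise ValueError(f"{path}:{lineno}: coordinates must be >= 1")
            orf = parts[3].strip()
            if not orf:
                raise ValueError(f"{path}:{lineno}: empty ORF name")
            gene = parts[4].strip() if len(parts) == 5 and parts[4].strip() else None
            pos = (plate, row, col)
            if pos in entries:
                raise ValueError(f"{path}:{lineno}: duplicate position {pos}")
            entries[pos] = (orf, gene)
    key = ArrayKey(entries=entries)
    if features:
        key.backfill_genes(features)
    return key


def load_feature_table(path: str | Path,
                       orf_column: int = 3,
                       gene_column: int = 4,
                       description_column: int = 15,
                       ) -> tuple[dict[str, str], dict[str, str]]:
    """Parse an SGD_features.tab-style table.

    Returns (orf -> standard gene name, orf -> description).  Column
    indices follow the public SGD feature-table layout (0-based:
    systematic name in column 3, standard name in column 4, description
    in column 15), but are configurable for trimmed tables.
    """
    genes: dict[str, str] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) <= orf_column:
                continue
            orf = parts[orf_column].strip()
            if not orf:
                continue
            if len(parts) > gene_column and parts[gene_column].strip():
                genes[orf] = parts[gene_column].strip()
            if len(parts) > description_column and parts[description_column].strip():
                descriptions[orf] = parts[description_column].strip()
    return genes, descriptions


@dataclass
class SetCatalogue:
    """Raw files in a folder grouped by base name and set number."""

    # base_name -> set_number -> {plate_number: path}
    groups: dict[str, dict[int, dict[int, Path]]]
    incomplete: list[str] = field(default_factory=list)

    def bases(self) -> list[str]:
        return sorted(self.groups)

    def sets(self, base: str) -> list[int]:
        return sorted(self.groups.get(base, {}))


def discover_sets(folder: str | Path) -> SetCatalogue:
    """Scan a folder of raw area files and group them into replicate
    sets by their embedded (base name, set, plate) metadata.  Sets
    whose plate list differs from the other sets of the same base are
    flagged as incomplete (diagnostics only)."""
    folder = Path(folder)
    groups: dict[str, dict[int, dict[int, Path]]] = defaultdict(
        lambda: defaultdict(dict))
    for path in sorted(folder.glob("*.txt")):
        try:
            pm = colony_quant.read_raw_file(path)
        except ValueError:
            continue
        groups[pm.base_name][pm.set_number][pm.plate_number] = path
    catalogue = SetCatalogue(groups={b: dict(s) for b, s in groups.items()})
    for base, sets in catalogue.groups.items():
        all_plates = set()
        for plates in sets.values():
            all_plates |= set(plates)
        for s, plates in sets.items():
            missing = all_plates - set(plates)
            if missing:
                catalogue.incomplete.append(
                    f"{base} set {s}: missing plates {sorted(missing)}")
    return catalogue


@dataclass
class ScoredSet:
    """One paired (control, experiment) replicate set, normalized.

    ``table`` has one row per array position with columns plate, row,
    col, orf, gene, ctrl, exp.
    """

    set_id: int
    control_set: int
    experiment_set: int
    table: pd.DataFrame


def _normalized_values(path: Path, corrections, **norm_kwargs) -> tuple[int, np.ndarray]:
    pm = colony_quant.read_raw_file(path)
    np_plate = normalization.normalize_plate(pm, corrections, **norm_kwargs)
    return pm.plate_number, np_plate.values


def pair_and_score(
    control_sets: dict[int, dict[int, Path]],
    experiment_sets: dict[int, dict[int, Path]],
    key: ArrayKey | None = None,
    corrections: tuple[str, ...] = ("row_column",),
    **norm_kwargs,
) -> list[ScoredSet]:
    """Normalize and align control/experiment sets plate by plate.

    Control set *i* is paired with experiment set *i* after sorting set
    numbers; when the two sides have different numbers of sets, the
    overlap is paired and the rest dropped with a warning entry.  Each
    plate is normalized independently before positions are paired, so
    plate-to-plate growth differences cancel.
    """
    ctrl_ids = sorted(control_sets)
    exp_ids = sorted(experiment_sets)
    n_pairs = min(len(ctrl_ids), len(exp_ids))
    out: list[ScoredSet] = []
    for k in range(n_pairs):
        ci, ei = ctrl_ids[k], exp_ids[k]
        ctrl_plates = control_sets[ci]
        exp_plates = experiment_sets[ei]
        if set(ctrl_plates) != set(exp_plates):
            raise ValueError(
                f"plate mismatch between control set {ci} "
                f"({sorted(ctrl_plates)}) and experiment set {ei} "
                f"({sorted(exp_plates)})")
        rows_out = []
        for p in sorted(ctrl_plates):
            _, cv = _normalized_values(ctrl_plates[p], corrections, **norm_kwargs)
            _, ev = _normalized_values(exp_plates[p], corrections, **norm_kwargs)
            if cv.shape != ev.shape:
                raise ValueError(
                    f"grid dimension mismatch on plate {p}: "
                    f"{cv.shape} vs {ev.shape}")
            nr, nc = cv.shape
            for r in range(nr):
                for c in range(nc):
                    orf = key.orf(p, r + 1, c + 1) if key else None
                    gene = key.gene(p, r + 1, c + 1) if key else None
                    rows_out.append((p, r + 1, c + 1, orf or "", gene or "",
                                     cv[r, c], ev[r, c]))
        table = pd.DataFrame(
            rows_out,
            columns=["plate", "row", "col", "orf", "gene", "ctrl", "exp"])
        out.append(ScoredSet(set_id=k + 1, control_set=ci,
                             experiment_set=ei, table=table))
    return out


def _aggregate_by_orf(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) of duplicate ORFs."""
    grouped = table.groupby("orf", sort=True)
    agg = grouped.agg(
        gene=("gene", "first"),
        plate=("plate", "first"),
        row=("row", "first"),
        col=("col", "first"),
        ctrl=("ctrl", "mean"),
        ctrl_sd=("ctrl", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
        exp=("exp", "mean"),
        exp_sd=("exp", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
    ).reset_index()
    return agg[SCORED_COLUMNS]


def write_scored(
    sets: list[ScoredSet],
    out_dir: str | Path,
    base_name: str = "scored",
    mode_rows: str = "by_position",
    mode_sets: str = "per_set",
) -> list[Path]:
    """Write scored tables as tab-delimited files.

    ``mode_rows``: ``by_position`` keeps one row per grid position;
    ``by_orf`` aggregates duplicate ORFs within each output (mean and
    sample SD).  ``mode_sets``: ``per_set`` writes one file per paired
    set (required downstream for paired t-tests); ``combined``
    aggregates replicate values across sets (mean and sample SD per
    position or ORF).
    """
    if not sets:
        raise ValueError("no scored sets to write")
    if mode_rows not in ("by_position", "by_orf"):
        raise ValueError(f"unknown mode_rows {mode_rows!r}")
    if mode_sets not in ("per_set", "combined"):
        raise ValueError(f"unknown mode_sets {mode_sets!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(df: pd.DataFrame, path: Path) -> None:
        df = df.copy()
        for col in ("ctrl", "ctrl_sd", "exp", "exp_sd"):
            df[col] = df[col].map(lambda v: f"{v:.6g}")
        df.to_csv(path, sep="\t", index=False)
        written.append(path)

    if mode_sets == "per_set":
        for ss in sets:
            df = ss.table.copy()
            df["ctrl_sd"] = 0.0
            df["exp_sd"] = 0.0
            df = df[SCORED_COLUMNS]
            if mode_rows == "by_orf":
                df = _aggregate_by_orf(ss.table.assign(ctrl_sd=0.0, exp_sd=0.0))
            _emit(df, out_dir / f"{base_name}_set-{ss.set_id}.txt")
    else:
        combined = pd.concat([ss.table for ss in sets], ignore_index=True)
        if mode_rows == "by_orf":
            df = _aggregate_by_orf(combined)
        else:
            grouped = combined.groupby(["plate", "row", "col"], sort=True)
            df = grouped.agg(
                orf=("orf", "first"),
                gene=("gene", "first"),
                ctrl=("ctrl", "mean"),
                ctrl_sd=("ctrl", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
                exp=("exp", "mean"),
                exp_sd=("exp", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
            ).reset_index()[SCORED_COLUMNS]
        _emit(df, out_dir / f"{base_name}_combined.txt")
    return written


def read_scored(path: str | Path) -> pd.DataFrame:
    """Read a scored table written by :func:`write_scored`."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"plate": int, "row": int, "col": int},
                     keep_default_na=False)
    missing = set(SCORED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("ctrl", "ctrl_sd", "exp", "exp_sd"):
        df[col] = pd.to_numeric(df[col])
    return df
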