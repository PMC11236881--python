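"""CSV readers and writers for the exchange formats.

All files are comma-separated UTF-8 with a mandatory header and '.' decimal.
Every writer/reader pair round-trips values to full float precision
(repr-based formatting).
"""

from __future__ import annotations

import json
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    _MISSING_TOKENS,
    AMatrix,
    CVResult,
    ECTable,
    MeanSet,
    PedigreeTable,
    TrialDataset,
)

log = logging.getLogger(__name__)

KG_PER_TONNE = 1000.0


def read_plot_data(path, unit: str = "kg/ha") -> list[TrialDataset]:
    """Read plot-level phenotype records, one :class:`TrialDataset` per location.

    Expected columns: ``location, genotype, replicate, row, column, yield``.
    Empty yield cells are kept as missing plots; non-numeric yields raise with
    the offending line number.
    """
    df = pd.read_csv(path, dtype={"location": str, "genotype": str})
    required = ["location", "genotype", "replicate", "row", "column", "yield"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    y = pd.to_numeric(df["yield"], errors="coerce")
    bad = y.isna() & df["yield"].notna() & (df["yield"].astype(str).str.strip() != "")
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValueError(f"{path}: non-numeric yield value on line {line}")
    df = df.assign(yield_value=y)
    out = []
    for loc in sorted(df["location"].unique()):
        sub = df[df["location"] == loc].reset_index(drop=True)
        layout = (int(sub["row"].max()), int(sub["column"].max()),
                  int(sub["replicate"].max()))
        out.append(TrialDataset(
            location=loc,
            data=sub[["genotype", "replicate", "row", "column", "yield_value"]].copy(),
            layout=layout,
            unit=unit,
        ))
    return out


def _norm_parent(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return None if s.lower() in _MISSING_TOKENS else s


def read_pedigree(path) -> PedigreeTable:
    """Read pedigree records ``genotype,parent1,parent2``.

    Unknown parents (empty/NA/0) are normalized to None. Parents that never
    appear as a genotype are auto-added as founders. Cycles raise.
    """
    df = pd.read_csv(path, dtype=str)
    required = ["genotype", "parent1", "parent2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    rows = []
    seen = set()
    for _, r in df.iterrows():
        g = str(r["genotype"]).strip()
        if g in seen:
            raise ValueError(f"{path}: duplicate pedigree entry for {g!r}")
        seen.add(g)
        rows.append((g, _norm_parent(r["parent1"]), _norm_parent(r["parent2"])))
    return build_pedigree(rows)


def build_pedigree(rows: Sequence[tuple[str, str | None, str | None]]) -> PedigreeTable:
    """Build a :class:`PedigreeTable` from (genotype, parent1, parent2) tuples,
    auto-completing missing parents as founders and checking acyclicity."""
    known = {g for g, _, _ in rows}
    completed = list(rows)
    added = []
    for _, p1, p2 in rows:
        for p in (p1, p2):
            if p is not None and p not in known:
                known.add(p)
                added.append(p)
                completed.append((p, None, None))
    if added:
        log.info("pedigree: auto-added %d parents as founders: %s",
                 len(added), added[:10])
    _check_acyclic(completed)
    entries = pd.DataFrame(completed, columns=["genotype", "parent1", "parent2"])
    return PedigreeTable(entries=entries)


def _check_acyclic(rows) -> None:
    parents = {g: [p for p in (p1, p2) if p is not None] for g, p1, p2 in rows}
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(g, stack):
        if state.get(g) == 1:
            return
        if state.get(g) == 0:
            cycle = stack[stack.index(g):] + [g]
            raise ValueError(f"pedigree cycle detected: {' -> '.join(cycle)}")
        state[g] = 0
        for p in parents.get(g, ()):
            visit(p, stack + [g])
        state[g] = 1

    for g in parents:
        visit(g, [])


def read_ec_table(path) -> ECTable:
    """Read a locations x covariates table (first column: location id).

    Missing cells raise (no imputation). Constant-valued covariates are
    dropped with a warning since they carry no information after
    standardization.
    """
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        cell = df.stack(future_stack=True)
        bad = cell[cell.isna()].index[0]
        raise ValueError(f"{path}: missing EC value at location={bad[0]!r}, "
                         f"covariate={bad[1]!r} (no imputation performed)")
    constant = [c for c in df.columns if df[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping {len(constant)} constant EC column(s): "
                      f"{constant[:10]}", stacklevel=2)
        df = df.drop(columns=constant)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no informative EC columns remain")
    return ECTable(locations=[str(i) for i in df.index],
                   covariate_names=[str(c) for c in df.columns],
                   values=df.to_numpy(dtype=float))


def read_means(path) -> list[MeanSet]:
    """Read Stage II input means (``location, genotype, mean_t_ha[, weight]``).

    The weight column is optional; absent weights default to 1 with a warning
    (unweighted Stage II analysis).
    """
    df = pd.read_csv(path, dtype={"location": str, "genotype": str},
                     float_precision="round_trip")
    required = ["location", "genotype", "mean_t_ha"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "weight" not in df.columns:
        warnings.warn(f"{path}: no 'weight' column; defaulting all Stage II "
                      "weights to 1 (unweighted analysis)", stacklevel=2)
        df = df.assign(weight=1.0)
    out = []
    for loc in sorted(df["location"].unique()):
        sub = df[df["location"] == loc]
        out.append(MeanSet(location=loc,
                           genotypes=[str(g) for g in sub["genotype"]],
                           means=sub["mean_t_ha"].to_numpy(dtype=float),
                           weights=sub["weight"].to_numpy(dtype=float)))
    return out


def write_means(mean_sets: Sequence[MeanSet], path) -> None:
    rows = []
    for ms in mean_sets:
        for g, m, w in zip(ms.genotypes, ms.means, ms.weights):
            rows.append((ms.location, g, repr(float(m)), repr(float(w))))
    pd.DataFrame(rows, columns=["location", "genotype", "mean_t_ha", "weight"]) \
        .to_csv(path, index=False)


def write_ec_table(ec: ECTable, path) -> None:
    df = ec.to_frame().map(lambda v: repr(float(v)))
    df.index.name = "location"
    df.to_csv(path)


def write_pedigree(ped: PedigreeTable, path) -> None:
    df = ped.entries.fillna("")
    df.to_csv(path, index=False)


def write_amatrix_sparse(A: AMatrix, path, threshold: float = 0.0) -> None:
    """Export A as a 3-column sparse CSV (row genotype, col genotype, value);
    only the lower triangle with |value| > threshold is written."""
    rows = []
    for i, gi in enumerate(A.genotypes):
        for j in range(i + 1):
            v = A.values[i, j]
            if abs(v) > threshold:
                rows.append((gi, A.genotypes[j], repr(float(v))))
    pd.DataFrame(rows, columns=["genotype_row", "genotype_col", "value"]) \
        .to_csv(path, index=False)


def write_cv_report(results: Sequence[CVResult], path) -> None:
    """Serialize a list of CV results as JSON (one record per model run)."""
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in results], fh, indent=2)


def convert_means_to_tonnes(mean_sets: Sequence[MeanSet], unit: str) -> list[MeanSet]:
    """Convert means (and weights) from the given unit to t/ha.

    Dividing means by 1000 divides their variances by 1e6, hence multiplies
    inverse-variance weights by 1e6.
    """
    if unit == "t/ha":
        return list(mean_sets)
    if unit != "kg/ha":
        raise ValueError(f"unknown yield unit {unit!r}")
    log.info("converting %d mean sets from kg/ha to t/ha", len(mean_sets))
    c = KG_PER_TONNE
    return [MeanSet(m.location, list(m.genotypes), m.means / c, m.weights * c * c)
            for m in mean_sets]


def drop_genotypes_without_pedigree(
    mean_sets: Sequence[MeanSet], A: AMatrix
) -> tuple[list[MeanSet], list[str]]:
    """Restrict Stage II means to genotypes present in the kinship matrix.

    Mirrors the practice of dropping checks without pedigree records between
    Stage I and Stage II. Returns the reduced mean sets and the drop list.
    """
    known = set(A.genotypes)
    dropped = sorted({g for ms in mean_sets for g in ms.genotypes if g not in known})
    if dropped:
        log.info("dropping %d genotype(s) without pedigree: %s",
                 len(dropped), dropped[:10])
        mean_sets = [ms.subset([g for g in ms.genotypes if g in known])
                     for ms in mean_sets]
    return list(mean_sets), dropped
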