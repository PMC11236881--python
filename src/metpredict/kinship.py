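"""Pedigree-based numerator relationship matrix (the kinship matrix A).

A[i, j] is twice the coefficient of coancestry: the expected proportion of
alleles shared identical-by-descent between i and j under the pedigree.
Multiplied by the additive genetic variance it gives the genetic covariance
between genotypes, so A plays the role of the genotype covariance structure
in the Stage II models that use pedigree information.

Construction uses the tabular (recursive) method in topological order:

    A_ii = 1 + 0.5 * A_{p1, p2}          (inbreeding from related parents)
    A_ij = 0.5 * (A_{j, p1} + A_{j, p2})  for j processed before i

with terms for unknown parents contributing 0. Unknown-parent founders are
assumed unrelated; by default they are assumed non-inbred (diagonal 1), with
an option to treat them as fully inbred lines (diagonal 2), the typical
state of advanced selfing-crop material. Selfing is encoded as
parent1 == parent2.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import AMatrix, PedigreeTable

log = logging.getLogger(__name__)


def sort_pedigree(ped: PedigreeTable) -> PedigreeTable:
    """Topologically sort pedigree entries so parents precede offspring.

    Stable: among entries whose parents are all placed, the original file
    order is kept. Raises on cycles.
    """
    entries = ped.entries
    genotypes = list(entries["genotype"])
    parents = {r.genotype: [p for p in (r.parent1, r.parent2) if p is not None]
               for r in entries.itertuples()}
    unknown = [p for ps in parents.values() for p in ps if p not in parents]
    if unknown:
        raise ValueError(f"pedigree references parents with no entry: {unknown[:5]}; "
                         "complete the pedigree first (see io.build_pedigree)")
    placed: set[str] = set()
    order: list[str] = []
    pending = list(genotypes)
    while pending:
        ready = [g for g in pending if all(p in placed for p in parents[g])]
        if not ready:
            raise ValueError(f"pedigree cycle among: {pending[:10]}")
        order.extend(ready)
        placed.update(ready)
        pending = [g for g in pending if g not in placed]
    idx = entries.set_index("genotype")
    sorted_entries = idx.loc[order].reset_index()
    return PedigreeTable(entries=sorted_entries, no_pedigree=list(ped.no_pedigree))


def numerator_relationship(ped: PedigreeTable,
                           founders_inbred: bool = False) -> AMatrix:
    """Build the numerator relationship matrix by the tabular method.

    Parameters
    ----------
    ped:
        Complete pedigree (every named parent has an entry).
    founders_inbred:
        If True, unknown-parent founders get diagonal 2 (fully inbred lines)
        instead of the default 1 (non-inbred).

    Returns
    -------
    AMatrix with genotypes in canonical (sorted) order.
    """
    sp = sort_pedigree(ped)
    order = list(sp.entries["genotype"])
    pos = {g: k for k, g in enumerate(order)}
    p1 = [pos.get(p) if p is not None else None for p in sp.entries["parent1"]]
    p2 = [pos.get(p) if p is not None else None for p in sp.entries["parent2"]]
    n = len(order)
    A = np.zeros((n, n))
    for i in range(n):
        a, b = p1[i], p2[i]
        if a is None and b is None:
            A[i, i] = 2.0 if founders_inbred else 1.0
        else:
            A[i, i] = 1.0 + 0.5 * (A[a, b] if (a is not None and b is not None) else 0.0)
        for j in range(i):
            v = 0.0
            if a is not None:
                v += 0.5 * A[j, a]
            if b is not None:
                v += 0.5 * A[j, b]
            A[i, j] = A[j, i] = v
    canon = sorted(order)
    sel = np.array([pos[g] for g in canon])
    return AMatrix(canon, A[np.ix_(sel, sel)])


def submatrix(A: AMatrix, genotypes: Sequence[str]) -> AMatrix:
    """Principal submatrix of A for the requested genotypes (canonical order)."""
    return A.submatrix(genotypes)


def ensure_positive_definite(values: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Return a Cholesky-factorizable version of a nominally-PSD matrix.

    If the Cholesky factorization fails, a ridge ``eps`` is added to the
    diagonal (logged); used before Kronecker products in simulation and
    model assembly.
    """
    try:
        np.linalg.cholesky(values)
        return values
    except np.linalg.LinAlgError:
        log.warning("matrix not positive definite; adding ridge %.1e to diagonal", eps)
        return values + eps * np.eye(values.shape[0])


def identity_amatrix(genotypes: Sequence[str]) -> AMatrix:
    """Identity relationship matrix (unrelated, non-inbred genotypes)."""
    g = sorted(genotypes)
    return AMatrix(g, np.eye(len(g)))
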