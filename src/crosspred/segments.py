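"""Pedigree relationships and the number of independent chromosome segments.

M_e = 1 / Var(G_ij - A_ij): the reciprocal variance of the deviations of
realized genomic relationships from their pedigree expectations over a
designated set of individual pairs.  Within a population the variance is
taken over all pairs; across populations over all (population 1,
population 2) pairs — when two populations form the reference they are
pooled into one pair set.  Strong LD / close relatedness makes G track A
tightly, giving a small variance and a small M_e; across populations the
absence of close relatives and the divergence of LD patterns make M_e
much larger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from crosspred.popsim import UNKNOWN_PARENT


@dataclass
class MeEstimate:
    me: float
    variance_of_difference: float
    pair_set: str
    n_pairs: int


def compute_a_matrix(pedigree: pd.DataFrame):
    """Expected additive relationships by the tabular method.

    A_ii = 1 + 0.5 A(sire_i, dam_i); A_ij = 0.5 (A(j, sire_i) +
    A(j, dam_i)) for j processed before i; unknown parents contribute 0.
    Individuals are processed in generation order, so parents precede
    offspring; different populations share no recorded ancestor and thus
    get A = 0 between them.

    Returns (A, ids) with ids in processing order.
    """
    ped = pedigree.sort_values("generation", kind="stable").reset_index(drop=True)
    ids = ped["individual_id"].to_numpy(dtype=object)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids in pedigree")
    pos = {iid: i for i, iid in enumerate(ids)}

    def parent_index(row_i, parent_id):
        if parent_id in (None, UNKNOWN_PARENT) or pd.isna(parent_id):
            return -1
        if parent_id == ids[row_i]:
            raise ValueError(f"individual {parent_id!r} is listed as its own ancestor")
        j = pos.get(parent_id, -1)
        if j >= row_i:
            raise ValueError(f"parent {parent_id!r} does not precede its "
                             f"offspring {ids[row_i]!r}; pedigree is not in "
                             "generation order (possible cycle)")
        return j

    n = len(ids)
    sire = np.array([parent_index(i, s) for i, s in enumerate(ped["sire_id"])])
    dam = np.array([parent_index(i, d) for i, d in enumerate(ped["dam_id"])])
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += A[:i, s]
            if d >= 0:
                row += A[:i, d]
            row *= 0.5
            A[:i, i] = row
            A[i, :i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A, ids


def _pair_differences(G, A, rows, cols):
    d = (G[np.ix_(rows, cols)] - A[np.ix_(rows, cols)]).ravel()
    return d


def estimate_me(G: np.ndarray, A: np.ndarray, ids, reference_ids,
                candidate_ids=None, mode: str = "cross") -> MeEstimate:
    """M_e = 1 / Var(G_ij - A_ij) over the designated pair set.

    mode "cross": all (reference, candidate) pairs — the id sets must be
    disjoint; a combined two-population reference is simply passed as
    one pooled reference id set.  mode "within": all unordered distinct
    pairs among ``reference_ids``.  The variance uses divisor N.
    """
    ids = np.asarray(ids, dtype=object)
    pos = {iid: i for i, iid in enumerate(ids)}
    G = np.asarray(G, dtype=float)
    A = np.asarray(A, dtype=float)
    if G.shape != A.shape or G.shape != (len(ids), len(ids)):
        raise ValueError("G, A and ids must be aligned")

    ref = np.array([pos[i] for i in reference_ids], dtype=int)
    if mode == "cross":
        if candidate_ids is None:
            raise ValueError("cross mode needs candidate ids")
        if set(reference_ids) & set(candidate_ids):
            raise ValueError("reference and candidate ids must be disjoint "
                             "for the across-pairs mode")
        cand = np.array([pos[i] for i in candidate_ids], dtype=int)
        diffs = _pair_differences(G, A, ref, cand)
        desc = f"cross ({len(ref)} reference x {len(cand)} candidates)"
    elif mode == "within":
        D = G[np.ix_(ref, ref)] - A[np.ix_(ref, ref)]
        iu = np.triu_indices(len(ref), k=1)
        diffs = D[iu]
        desc = f"within ({len(ref)} individuals, all unordered pairs)"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if len(diffs) < 2:
        raise ValueError("need at least 2 pairs to take a variance")
    var = float(np.var(diffs))  # divisor N
    if var == 0.0:
        raise ValueError("zero variance of G - A over the pair set: M_e is "
                         "infinite (are G and A identical on these pairs?)")
    return MeEstimate(me=1.0 / var, variance_of_difference=var,
                      pair_set=desc, n_pairs=len(diffs))
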