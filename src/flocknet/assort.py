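"""Weighted categorical assortment with jackknife SE and permutation p.

The assortment coefficient generalises Newman's categorical assortativity
to weighted graphs.  Build the mixing matrix

    e_kl = sum over dyads (i, j) of w_ij [c_i = k][c_j = l] / (2 W)

over ordered pairs (so e is symmetric), with W the total edge weight.
With marginals a_k = sum_l e_kl the coefficient is

    r = (sum_k e_kk - sum_k a_k^2) / (1 - sum_k a_k^2).

r = 1 when all edge weight lies within categories; r ~ 0 when weights are
independent of the labels.  The standard error is a delete-one-edge
jackknife, and significance comes from node-label permutations constrained
to each room (families and pairs never span rooms, and the rooms are
disconnected blocks of the network).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .network import AssociationMatrix
from .simulate import BirdRecord

__all__ = [
    "AssortmentResult",
    "weighted_assortment",
    "jackknife_se",
    "assortment_test",
    "family_assortment",
    "pair_assortment",
]


@dataclass(frozen=True)
class AssortmentResult:
    attribute: str
    r: float
    se: float
    p: float
    n_edges: int
    n_perms: int


def _mixing_r(w: np.ndarray, codes: np.ndarray, n_cat: int) -> float:
    m = np.zeros((len(codes), n_cat))
    m[np.arange(len(codes)), codes] = 1.0
    e = m.T @ w @ m
    total = e.sum()
    if total == 0:
        raise ValueError("no positive edge weight; assortment undefined")
    e /= total
    a = e.sum(axis=1)
    denom = 1.0 - a @ a
    if denom == 0:
        raise ValueError("all weight within one category; assortment undefined")
    return float((np.trace(e) - a @ a) / denom)


def weighted_assortment(a: AssociationMatrix,
                        labels: Mapping[str, object]) -> float:
    """Weighted categorical assortment coefficient of the network under a
    node labelling (e.g. family id, pair id)."""
    cats = sorted({labels[t] for t in a.tags}, key=str)
    code = {c: k for k, c in enumerate(cats)}
    codes = np.asarray([code[labels[t]] for t in a.tags])
    return _mixing_r(a.weights, codes, len(cats))


def jackknife_se(a: AssociationMatrix, labels: Mapping[str, object]) -> float:
    """Delete-one-edge jackknife SE of the assortment coefficient.

    Each positive edge is removed in turn and r recomputed;
    se = sqrt(((m - 1)/m) * sum (r_(-e) - mean)^2) over the m edges.
    """
    cats = sorted({labels[t] for t in a.tags}, key=str)
    code = {c: k for k, c in enumerate(cats)}
    codes = np.asarray([code[labels[t]] for t in a.tags])
    iu, ju = np.nonzero(np.triu(a.weights, 1))
    m = iu.size
    if m < 2:
        raise ValueError("jackknife needs at least 2 positive edges")
    r_del = np.empty(m)
    w = a.weights.copy()
    for e in range(m):
        i, j = iu[e], ju[e]
        saved = w[i, j]
        w[i, j] = w[j, i] = 0.0
        r_del[e] = _mixing_r(w, codes, len(cats))
        w[i, j] = w[j, i] = saved
    return float(np.sqrt((m - 1) / m * ((r_del - r_del.mean()) ** 2).sum()))


def assortment_test(
    a: AssociationMatrix,
    labels: Mapping[str, object],
    attribute: str = "label",
    n_perms: int = 1000,
    seed: int = 0,
) -> AssortmentResult:
    """Assortment coefficient with jackknife SE and a two-tailed node-label
    permutation p-value.

    Labels are shuffled among nodes within each room (1000 draws by
    default) and the observed r is located within the null distribution,
    two-tailed around the null's own centre with the add-one estimator:
    p = (1 + #{|r_null - c| >= |r_obs - c|}) / (n_perms + 1).  The null is
    generally not centred at zero — singleton categories (e.g. chicks in a
    pair labelling) pull it negative — so deviations are measured from the
    null centre rather than from zero.
    """
    r_obs = weighted_assortment(a, labels)
    se = jackknife_se(a, labels)
    rng = np.random.default_rng(seed)
    cats = sorted({labels[t] for t in a.tags}, key=str)
    code = {c: k for k, c in enumerate(cats)}
    codes = np.asarray([code[labels[t]] for t in a.tags])
    rooms = np.asarray(a.rooms)
    room_idx = [np.flatnonzero(rooms == r) for r in sorted(set(a.rooms))]
    null = []
    for _ in range(n_perms):
        perm = codes.copy()
        for idx in room_idx:
            perm[idx] = perm[rng.permutation(idx)]
        try:
            null.append(_mixing_r(a.weights, perm, len(cats)))
        except ValueError:
            continue
    null_arr = np.asarray(null)
    c = float(null_arr.mean()) if null_arr.size else 0.0
    k = int(np.sum(np.abs(null_arr - c) >= abs(r_obs - c) - 1e-12))
    n_edges = int((np.triu(a.weights, 1) > 0).sum())
    return AssortmentResult(attribute, r_obs, se, (k + 1) / (null_arr.size + 1),
                            n_edges, int(null_arr.size))


def family_assortment(
    a: AssociationMatrix,
    roster: Sequence[BirdRecord],
    chicks_only: bool = False,
    n_perms: int = 1000,
    seed: int = 0,
) -> AssortmentResult:
    """Assortment by family membership.

    By default every within-family edge counts (parent-parent, parent-chick
    and chick-chick).  With ``chicks_only`` parents get unique singleton
    labels so only chick-chick family edges contribute to the diagonal.
    """
    labels: dict[str, object] = {}
    for b in roster:
        if chicks_only and b.role != "chick":
            labels[b.tag] = f"solo_{b.tag}"
        else:
            labels[b.tag] = b.family_id
    return assortment_test(a, labels, "family", n_perms, seed)


def pair_assortment(
    a: AssociationMatrix,
    roster: Sequence[BirdRecord],
    n_perms: int = 1000,
    seed: int = 0,
) -> AssortmentResult:
    """Assortment by mated pair: paired adults share a pair label, all
    other birds get unique singleton labels."""
    pairs = [b for b in roster if b.role == "parent" and b.mate_tag]
    if len(pairs) < 4:
        raise ValueError("need at least 2 mated pairs")
    labels: dict[str, object] = {}
    for b in roster:
        if b.role == "parent" and b.mate_tag:
            labels[b.tag] = "pair_" + "".join(sorted([b.tag, b.mate_tag]))
        else:
            labels[b.tag] = f"solo_{b.tag}"
    return assortment_test(a, labels, "pair", n_perms, seed)
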