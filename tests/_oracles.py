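"""Independent brute-force oracles used to pin down expected values.

These deliberately avoid the implementation's code paths (binary
convolution powers, linprog, scipy rank tests): MIDs are enumerated
atom-by-atom or unit-by-unit with dict-based polynomial accumulation, LPs
are solved by basic-feasible-solution enumeration, and rank-test p-values
by enumerating label assignments.
"""

from __future__ import annotations

import itertools
import math
from collections import defaultdict

import numpy as np

P13C = 0.0107

ELEMENT_DISTS = {
    "C": [1 - P13C, P13C],
    "H": [0.999885, 0.000115],
    "O": [0.99757, 0.00038, 0.00205],
    "N": [0.99636, 0.00364],
}


def _accumulate(dists) -> dict[int, float]:
    """Distribution of the sum of independent integer masses (dict algebra)."""
    acc = {0: 1.0}
    for dist in dists:
        new: dict[int, float] = defaultdict(float)
        for m, pm in acc.items():
            for mm, pd in enumerate(dist):
                if pd:
                    new[m + mm] += pm * pd
        acc = dict(new)
    return acc


def _to_vector(acc: dict[int, float], n_tracked: int) -> np.ndarray:
    out = np.zeros(n_tracked + 1)
    for m, p in acc.items():
        if m <= n_tracked:
            out[m] += p
    return out / out.sum()


def natural_mid_bitmask(n_carbons: int, n_tracked: int) -> np.ndarray:
    """Natural-abundance MID of a carbon-only molecule by exhaustive
    enumeration of all 2^n label placements collapsed by mass."""
    masses = np.array(
        [bin(mask).count("1") for mask in range(2**n_carbons)], dtype=int
    )
    weights = P13C ** masses * (1 - P13C) ** (n_carbons - masses)
    out = np.zeros(n_tracked + 1)
    for m, w in zip(masses, weights):
        if m <= n_tracked:
            out[m] += w
    return out / out.sum()


def _formula_atoms(formula_counts: dict[str, int]):
    for element, n in sorted(formula_counts.items()):
        for _ in range(n):
            yield ELEMENT_DISTS[element]


def synthesized_mid_enumeration(
    D: float,
    n_units: int,
    formula_counts: dict[str, int],
    n_tracked: int,
    tracer_labels: int = 1,
    tracer_purity: float = 0.99,
    unit_carbons: int = 2,
    natural_abundance: bool = True,
) -> np.ndarray:
    """Polymer MID by brute force over all 2^n_units tracer assignments.

    Each unit contributes atom-level distributions; remaining formula atoms
    are appended at natural abundance.
    """
    remainder = dict(formula_counts)
    remainder["C"] = remainder.get("C", 0) - unit_carbons * n_units
    assert remainder["C"] >= 0
    total: dict[int, float] = defaultdict(float)
    for assignment in itertools.product([False, True], repeat=n_units):
        weight = 1.0
        atom_dists = []
        for is_tracer in assignment:
            weight *= D if is_tracer else (1 - D)
            if is_tracer:
                for _ in range(tracer_labels):
                    atom_dists.append([1 - tracer_purity, tracer_purity])
                for _ in range(unit_carbons - tracer_labels):
                    atom_dists.append(
                        ELEMENT_DISTS["C"] if natural_abundance else [1.0]
                    )
            else:
                for _ in range(unit_carbons):
                    atom_dists.append(
                        ELEMENT_DISTS["C"] if natural_abundance else [1.0]
                    )
        if weight == 0.0:
            continue
        if natural_abundance:
            atom_dists.extend(_formula_atoms(remainder))
        for m, p in _accumulate(atom_dists).items():
            total[m] += weight * p
    return _to_vector(total, n_tracked)


def vertex_enumeration_optimum(model) -> float:
    """Max objective over all basic feasible solutions of the FBA LP."""
    S = model.stoichiometric_matrix().to_numpy()
    rxn_ids = [r.id for r in model.reactions]
    n = S.shape[1]
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    obj = rxn_ids.index(model.objective)
    rank = np.linalg.matrix_rank(S)
    best = None
    for free in itertools.combinations(range(n), n - rank):
        basic = [j for j in range(n) if j not in free]
        SB = S[:, basic]
        if np.linalg.matrix_rank(SB) < rank:
            continue
        for corner in itertools.product(*[(lb[j], ub[j]) for j in free]):
            rhs = -S[:, list(free)] @ np.array(corner)
            vB, *_ = np.linalg.lstsq(SB, rhs, rcond=None)
            v = np.empty(n)
            v[list(free)] = corner
            v[basic] = vB
            if np.max(np.abs(S @ v)) > 1e-8:
                continue
            if np.any(v < lb - 1e-8) or np.any(v > ub + 1e-8):
                continue
            if best is None or v[obj] > best:
                best = float(v[obj])
    assert best is not None, "LP has no feasible vertex"
    return best


def exact_rank_sum_p(x, y) -> float:
    """Two-sided exact Wilcoxon rank-sum p by enumerating all assignments.

    p = 2 * min(P(U <= u_obs), P(U >= u_obs)) capped at 1, where U is the
    Mann-Whitney statistic of the first sample. Assumes no ties.
    """
    x = list(x)
    y = list(y)
    pooled = x + y
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    u_all = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u_all.append(sum(1 for xi in xs for yj in ys if xi > yj))
    u_all = np.array(u_all)
    p_low = np.mean(u_all <= u_obs)
    p_high = np.mean(u_all >= u_obs)
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def exhaustive_permanova_p(dist, groups) -> tuple[float, float]:
    """(observed pseudo-F, exact p) by enumerating distinct labelings."""
    d2 = np.asarray(dist, dtype=float) ** 2
    groups = np.asarray(groups)
    labels = sorted(set(groups))
    n = len(groups)
    k = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def pseudo_f(assign):
        ss_w = 0.0
        for lab in labels:
            idx = [i for i, g in enumerate(assign) if g == lab]
            pairs = [(i, j) for i, j in itertools.combinations(idx, 2)]
            ss_w += sum(d2[i, j] for i, j in pairs) / len(idx)
        return (ss_total - ss_w) / (k - 1) / (ss_w / (n - k))

    f_obs = pseudo_f(groups)
    f_all = [pseudo_f(p) for p in set(itertools.permutations(groups))]
    p = np.mean([f >= f_obs - 1e-12 for f in f_all])
    return float(f_obs), float(p)
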