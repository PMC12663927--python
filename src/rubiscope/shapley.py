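"""Exact Shapley attribution for shallow regression trees.

For a fitted decision tree f and an input x, the value of a feature
coalition S is the conditional expectation of the tree output when the
features in S are fixed to x and the rest are marginalised over the
training distribution as recorded in the tree itself:

    v(S) = E[f | x_S]

computed by a single traversal: at a node splitting on a feature in S
the branch chosen by x is followed; at a node splitting on any other
feature both children are averaged, weighted by their training-sample
counts.  The Shapley value of feature j is then the classic weighted
average of marginal contributions over all coalitions of the features
the tree actually uses.  Features not used by the tree receive exactly
zero and v({}) is the tree's base value, so local accuracy

    base + sum_j phi_j = f(x)

holds to machine precision.

Trees of depth <= 3 use at most 7 distinct split features, so the
2^|F| coalition enumeration is cheap and exact — no sampling and no
path-approximation is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
from sklearn.tree import DecisionTreeRegressor


@dataclass
class TreeAttribution:
    """Per-feature Shapley values for one input row."""

    base_value: float
    values: dict[int, float]  # feature index -> attribution

    @property
    def total(self) -> float:
        return self.base_value + sum(self.values.values())


class TreeExplainer:
    """Exact Shapley explainer for a fitted ``DecisionTreeRegressor``."""

    def __init__(self, tree: DecisionTreeRegressor):
        t = tree.tree_
        self.left = t.children_left
        self.right = t.children_right
        self.feature = t.feature
        self.threshold = t.threshold
        self.value = t.value[:, 0, 0]
        self.weight = t.weighted_n_node_samples
        self.features_used: tuple[int, ...] = tuple(
            sorted({int(f) for f in self.feature if f >= 0})
        )
        if len(self.features_used) > 25:
            raise ValueError(
                "exact coalition enumeration is intended for shallow trees "
                f"({len(self.features_used)} distinct split features)"
            )

    # -- conditional expectation traversal ---------------------------------
    def cond_exp(self, x: np.ndarray, coalition: frozenset[int]) -> float:
        """E[f | x_S] with S = ``coalition`` fixed to the values in x."""
        return self._walk(0, x, coalition)

    def _walk(self, node: int, x: np.ndarray, coalition: frozenset[int]) -> float:
        f = self.feature[node]
        if f < 0:  # leaf
            return float(self.value[node])
        lo, hi = self.left[node], self.right[node]
        if int(f) in coalition:
            child = lo if x[f] <= self.threshold[node] else hi
            return self._walk(child, x, coalition)
        wl, wh = self.weight[lo], self.weight[hi]
        return (
            wl * self._walk(lo, x, coalition) + wh * self._walk(hi, x, coalition)
        ) / (wl + wh)

    # -- exact Shapley over the used features -------------------------------
    def shap_values(self, x: np.ndarray) -> TreeAttribution:
        x = np.asarray(x, float).ravel()
        used = self.features_used
        m = len(used)
        # v(S) for every coalition, encoded as bitmasks over `used`
        v = np.empty(1 << m)
        for mask in range(1 << m):
            coalition = frozenset(used[k] for k in range(m) if mask >> k & 1)
            v[mask] = self._walk(0, x, coalition)
        # Shapley weights depend only on |S|
        w = [factorial(s) * factorial(m - s - 1) / factorial(m) for s in range(m)]
        phi: dict[int, float] = {}
        for k, feat in enumerate(used):
            bit = 1 << k
            total = 0.0
            for mask in range(1 << m):
                if mask & bit:
                    continue
                s = bin(mask).count("1")
                total += w[s] * (v[mask | bit] - v[mask])
            phi[feat] = total
        return TreeAttribution(base_value=float(v[0]), values=phi)

    def shap_matrix(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Dense (n_rows, n_features) Shapley matrix plus base values.

        Columns for features the tree never splits on are zero.
        """
        X = np.asarray(X, float)
        n, p = X.shape
        out = np.zeros((n, p))
        base = np.empty(n)
        for i in range(n):
            attr = self.shap_values(X[i])
            base[i] = attr.base_value
            for feat, val in attr.values.items():
                out[i, feat] = val
        return out, base


def shap_values_brute_force(
    explainer: TreeExplainer, x: np.ndarray
) -> TreeAttribution:
    """Independent Shapley computation by averaging marginal contributions
    over all orderings of the used features (O(m! * 2^m); test oracle)."""
    from itertools import permutations

    x = np.asarray(x, float).ravel()
    used = explainer.features_used
    phi = {f: 0.0 for f in used}
    orderings = list(permutations(used))
    for order in orderings:
        coalition: set[int] = set()
        for f in order:
            before = explainer.cond_exp(x, frozenset(coalition))
            coalition.add(f)
            after = explainer.cond_exp(x, frozenset(coalition))
            phi[f] += after - before
    k = len(orderings) or 1
    return TreeAttribution(
        base_value=explainer.cond_exp(x, frozenset()),
        values={f: v / k for f, v in phi.items()},
    )
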