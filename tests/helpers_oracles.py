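"""Independent naive-loop oracles for the sequence encoders and metrics.

These deliberately re-derive every quantity with plain Python loops straight
from the written definitions, sharing no code with the implementation, so
that agreement is a meaningful check.
"""

import math
from itertools import combinations

ALPHABET = "ACGU"
DINUCLEOTIDES = [a + b for a in ALPHABET for b in ALPHABET]


def oracle_enac(seq: str, window: int) -> list[float]:
    out = []
    for start in range(len(seq) - window + 1):
        chunk = seq[start : start + window]
        for nt in ALPHABET:
            out.append(chunk.count(nt) / window)
    return out


def oracle_cksnap(seq: str, max_gap: int) -> list[float]:
    out = []
    for k in range(max_gap + 1):
        pairs = [seq[i] + seq[i + k + 1] for i in range(len(seq) - k - 1)]
        for duo in DINUCLEOTIDES:
            out.append(pairs.count(duo) / len(pairs))
    return out


def oracle_anf(seq: str) -> list[float]:
    return [seq[: i + 1].count(seq[i]) / (i + 1) for i in range(len(seq))]


def oracle_ncp(seq: str) -> list[float]:
    code = {"A": (1, 1, 1), "C": (0, 1, 0), "U": (1, 0, 0), "G": (0, 0, 1)}
    return [bit for nt in seq for bit in code[nt]]


def oracle_binary(seq: str) -> list[float]:
    return [1.0 if nt == target else 0.0 for nt in seq for target in ALPHABET]


def oracle_scpsednc(seq: str, lam: int, weight: float, prop: dict[str, list[float]]):
    """prop maps each dinucleotide to its list of index values (already on the
    scale to be used, i.e. standardized upstream if desired)."""
    length = len(seq)
    n_idx = len(next(iter(prop.values())))
    dinucs = [seq[i : i + 2] for i in range(length - 1)]
    freqs = [dinucs.count(duo) / len(dinucs) for duo in DINUCLEOTIDES]
    thetas = []
    for m in range(1, lam + 1):  # tier-major: all indices within a tier
        for idx in range(n_idx):
            acc = [
                prop[dinucs[i]][idx] * prop[dinucs[i + m]][idx]
                for i in range(length - m - 2)
            ]
            thetas.append(sum(acc) / len(acc))
    denom = 1.0 + weight * sum(thetas)
    return [f / denom for f in freqs] + [weight * t / denom for t in thetas]


def oracle_word2vec(seq: str, model) -> list[float]:
    tokens = [seq[i : i + model.token_k] for i in range(len(seq) - model.token_k + 1)]
    acc = [0.0] * model.dim
    for tok in tokens:
        if tok in model.vocab:
            vec = model.vectors[model.vocab[tok]]
            for d in range(model.dim):
                acc[d] += vec[d]
    return [v / len(tokens) for v in acc]


def oracle_auroc(y_true, scores) -> float:
    """Mann-Whitney pair counting: fraction of (pos, neg) pairs correctly
    ordered, ties counted one half."""
    pos = [s for s, y in zip(scores, y_true) if y == 1]
    neg = [s for s, y in zip(scores, y_true) if y == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def oracle_auprc(y_true, scores) -> float:
    """Step-wise average precision by exhaustive threshold enumeration."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    tp = 0
    total_pos = sum(y_true)
    area = 0.0
    prev_recall = 0.0
    seen = 0
    for rank, i in enumerate(order, start=1):
        tp += y_true[i]
        seen = rank
        # only cut *between* distinct score values
        if rank < len(order) and scores[order[rank]] == scores[i]:
            continue
        recall = tp / total_pos
        precision = tp / seen
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def oracle_fscore(values, labels) -> float:
    pos = [v for v, y in zip(values, labels) if y == 1]
    neg = [v for v, y in zip(values, labels) if y == 0]
    both = list(values)
    mean = sum(both) / len(both)
    mp, mn = sum(pos) / len(pos), sum(neg) / len(neg)
    num = (mp - mean) ** 2 + (mn - mean) ** 2
    var_p = sum((v - mp) ** 2 for v in pos) / (len(pos) - 1)
    var_n = sum((v - mn) ** 2 for v in neg) / (len(neg) - 1)
    denom = var_p + var_n
    if denom == 0:
        return math.inf if num > 0 else 0.0
    return num / denom


def brute_force_tree_shapley(tree_dumps, x, n_features: int) -> list[float]:
    """Exact Shapley attributions by the exponential-sum definition.

    The conditional value of a coalition S follows the tree-path-dependent
    convention: at a node whose split feature is outside S, descend both
    children and average their values by training-cover weight.
    """

    def tree_value(tree, S):
        def rec(node):
            if "leaf" in node:
                return node["leaf"]
            feat = int(node["split"][1:])
            kids = {c["nodeid"]: c for c in node["children"]}
            if feat in S:
                branch = node["yes"] if x[feat] < node["split_condition"] else node["no"]
                return rec(kids[branch])
            total_cover = sum(c["cover"] for c in node["children"])
            return sum(c["cover"] * rec(c) for c in node["children"]) / total_cover

        return rec(tree)

    def value(S):
        return sum(tree_value(t, S) for t in tree_dumps)

    phis = []
    features = list(range(n_features))
    for i in features:
        others = [f for f in features if f != i]
        total = 0.0
        for r in range(len(others) + 1):
            for S in combinations(others, r):
                wgt = (
                    math.factorial(len(S))
                    * math.factorial(n_features - len(S) - 1)
                    / math.factorial(n_features)
                )
                total += wgt * (value(set(S) | {i}) - value(set(S)))
        phis.append(total)
    return phis
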