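"""Independent naive implementations used as test oracles.

Everything here is written as explicit double loops over plain Python
floats, deliberately sharing no code path with the package (which is
vectorized through scipy distance matrices).
"""

import cmath
import math


def naive_chebyshev(a, b):
    return max(abs(x - y) for x, y in zip(a, b))


def naive_embed(x, m, center=False):
    vecs = []
    for i in range(len(x) - m + 1):
        v = [float(x[i + k]) for k in range(m)]
        if center:
            mu = sum(v) / m
            v = [e - mu for e in v]
        vecs.append(v)
    return vecs


def naive_apen(x, m, s_coef, exclude_self=False):
    L = len(x)
    mu = sum(x) / L
    sd = math.sqrt(sum((v - mu) ** 2 for v in x) / L)
    s = s_coef * sd
    if s == 0:
        return 0.0

    def phi(k):
        T = naive_embed(x, k)
        n = len(T)
        total = 0.0
        for i in range(n):
            count = 0
            for j in range(n):
                if exclude_self and i == j:
                    continue
                if naive_chebyshev(T[i], T[j]) <= s:
                    count += 1
            total += math.log(count / n)
        return total / n

    return phi(m) - phi(m + 1)


def naive_sampen(x, m, s_coef):
    L = len(x)
    mu = sum(x) / L
    sd = math.sqrt(sum((v - mu) ** 2 for v in x) / L)
    s = s_coef * sd
    if s == 0:
        return 0.0

    def rate(k):
        T = naive_embed(x, k)[: L - m]
        n = len(T)
        total = 0.0
        for i in range(n):
            count = 0
            for j in range(n):
                if j != i and naive_chebyshev(T[i], T[j]) <= s:
                    count += 1
            total += count / (L - m - 1)
        return total / n

    B = rate(m)
    A = rate(m + 1)
    if A == 0 or B == 0:
        return float("nan")
    return math.log(B / A)


def naive_fuzzyen(x, m, s_coef, n_exp):
    L = len(x)
    mu = sum(x) / L
    sd = math.sqrt(sum((v - mu) ** 2 for v in x) / L)
    s = s_coef * sd
    if s == 0:
        return 0.0

    def gamma(k):
        T = naive_embed(x, k, center=True)[: L - m]
        n = len(T)
        total = 0.0
        for i in range(n):
            inner = 0.0
            for j in range(n):
                if j != i:
                    d = naive_chebyshev(T[i], T[j])
                    inner += math.exp(-(d**n_exp) / s)
            total += inner / (n - 1)
        return total / n

    return math.log(gamma(m)) - math.log(gamma(m + 1))


def naive_spectral_entropy(x):
    """Direct DFT periodogram (one-sided) + Shannon formula."""
    L = len(x)
    mu = sum(x) / L
    x = [v - mu for v in x]
    half = L // 2
    powers = []
    for k in range(half + 1):
        X = sum(x[t] * cmath.exp(-2j * math.pi * k * t / L) for t in range(L))
        p = abs(X) ** 2
        if 0 < k < L / 2:
            p *= 2.0
        powers.append(p)
    total = sum(powers)
    if total <= 0:
        return 0.0
    entropy = 0.0
    for p in powers:
        y = p / total
        if y > 0:
            entropy -= y * math.log(y)
    return entropy


def naive_auc_mann_whitney(y_true, scores):
    """Probability a random positive outscores a random negative (ties = 1/2)."""
    pos = [s for t, s in zip(y_true, scores) if t == 1]
    neg = [s for t, s in zip(y_true, scores) if t == -1]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def exhaustive_stump(X, y, w):
    """Best 1-D decision stump by exhaustive weighted-error search.

    Returns (error, threshold, left_label) minimizing weighted
    misclassification over all midpoint thresholds and label signs.
    """
    values = sorted(set(float(v) for v in X))
    thresholds = [(a + b) / 2 for a, b in zip(values, values[1:])]
    thresholds += [values[0] - 1, values[-1] + 1]
    best = None
    for t in thresholds:
        for left in (1, -1):
            err = sum(
                wi
                for xi, yi, wi in zip(X, y, w)
                if (left if xi <= t else -left) != yi
            )
            if best is None or err < best[0] - 1e-15:
                best = (err, t, left)
    return best
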