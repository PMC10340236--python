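"""Independent brute-force reference implementations of every descriptor.

Written deliberately as plain loops over definitions, sharing no code with
the package, so they can serve as oracles for the vectorised implementations.
"""

import math

import numpy as np

ORD = {"A": 1, "C": 2, "G": 3, "T": 4}
ORDERS = [(0, 0), (0, 1), (1, 0), (1, 1), (0, 2), (2, 0), (1, 2), (2, 1), (3, 0), (0, 3)]


def encode_naive(seq):
    return [ORD[c] for c in seq.upper() if c != "N"]


def square_naive(series):
    n = len(series)
    k = int(math.ceil(math.sqrt(n)))
    m = [[0] * k for _ in range(k)]
    for idx, val in enumerate(series):
        m[idx // k][idx % k] = val
    return np.array(m)


def raw_moments_naive(m):
    rows, cols = m.shape
    out = []
    for (i, j) in ORDERS:
        total = 0.0
        for b in range(1, rows + 1):
            for q in range(1, cols + 1):
                total += (b**i) * (q**j) * m[b - 1, q - 1]
        out.append(total)
    w00, w01, w10 = out[0], out[1], out[2]
    return np.array(out), (w10 / w00, w01 / w00)


def central_moments_naive(m, centroid):
    xbar, ybar = centroid
    rows, cols = m.shape
    out = []
    for (i, j) in ORDERS:
        total = 0.0
        for b in range(1, rows + 1):
            for q in range(1, cols + 1):
                total += ((b - xbar) ** i) * ((q - ybar) ** j) * m[b - 1, q - 1]
        out.append(total)
    return np.array(out)


def hahn_poly_naive(n, r, P, u=0.0, v=0.0):
    """Terminating 3F2 sum, evaluated term by term with exact rationals where
    possible (float arithmetic on small integers)."""

    def poch(a, k):
        prod = 1.0
        for t in range(k):
            prod *= a + t
        return prod

    return sum(
        poch(-n, k) * poch(n + u + v + 1, k) * poch(-r, k)
        / (poch(u + 1, k) * poch(1 - P, k) * math.factorial(k))
        for k in range(n + 1)
    )


def hahn_weight_naive(r, P, u=0.0, v=0.0):
    from scipy.special import gamma

    return (
        gamma(u + r + 1) * gamma(v + P - r)
        / (gamma(r + 1) * gamma(P - r) * gamma(u + 1) * gamma(v + 1))
    )


def hahn_basis_gram_schmidt(P, u=0.0, v=0.0, max_order=3):
    """Orthonormal basis from QR on weighted monomials — independent of any
    polynomial recurrence; spans the same nested spaces as the Hahn family."""
    r = np.arange(P, dtype=float)
    rho = np.array([hahn_weight_naive(ri, P, u, v) for ri in r])
    V = np.vstack([np.sqrt(rho) * r**k for k in range(max_order + 1)]).T
    q, rr = np.linalg.qr(V)
    return (q * np.sign(np.diag(rr))).T  # rows: orthonormal, positive leading coeff


def hahn_moments_naive(m, u=0.0, v=0.0):
    m = np.asarray(m, dtype=float)
    P = m.shape[0]
    if P < 4:
        pad = np.zeros((4, 4))
        pad[:P, :P] = m
        m, P = pad, 4
    r = np.arange(P, dtype=float)
    rho = np.array([hahn_weight_naive(ri, P, u, v) for ri in r])
    basis = []
    for n in range(4):
        h = np.array([hahn_poly_naive(n, ri, P, u, v) for ri in r])
        d2 = np.sum(rho * h * h)
        basis.append(h * np.sqrt(rho) / math.sqrt(d2))
    out = []
    for (x, y) in ORDERS:
        total = 0.0
        for i in range(P):
            for j in range(P):
                total += m[i, j] * basis[x][j] * basis[y][i]
        out.append(total)
    return np.array(out)


def prim_naive(seq, K=20):
    series = encode_naive(seq) if isinstance(seq, str) else list(seq)
    out = np.zeros((K, K), dtype=np.int64)
    for i in range(1, K + 1):
        first = None
        for p, s in enumerate(series, start=1):
            if s == i:
                first = p
                break
        if first is None:
            continue
        for j in range(1, K + 1):
            acc = 0
            for p, s in enumerate(series, start=1):
                if s == j and p > first:
                    acc += p - first
            out[i - 1, j - 1] = acc
    return out


def rprim_naive(seq, K=20):
    series = encode_naive(seq) if isinstance(seq, str) else list(seq)
    return prim_naive(list(reversed(series)), K)


def fdv_naive(seq, K=20):
    series = encode_naive(seq) if isinstance(seq, str) else list(seq)
    return np.array([series.count(i) for i in range(1, K + 1)], dtype=np.int64)


def aapiv_naive(seq, K=20):
    series = encode_naive(seq) if isinstance(seq, str) else list(seq)
    return np.array(
        [sum(p for p, s in enumerate(series, start=1) if s == i) for i in range(1, K + 1)],
        dtype=np.int64,
    )


def raapiv_naive(seq, K=20):
    series = encode_naive(seq) if isinstance(seq, str) else list(seq)
    return aapiv_naive(list(reversed(series)), K)


def metrics_naive(tp, tn, fp, fn):
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    return acc, sens, spec, mcc


def auc_mann_whitney(y_true, scores):
    """AUC as the rank statistic: P(score+ > score-) + 0.5 P(tie)."""
    pos = [s for s, t in zip(scores, y_true) if t == 1]
    neg = [s for s, t in zip(scores, y_true) if t == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def random_sequence(rng, max_len=64, min_len=2):
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list("ACGT"), size=n))
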