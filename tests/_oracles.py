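"""Independent brute-force oracles used to cross-check the production code.

Everything here is deliberately naive (explicit Python loops, no shared code
with the package) so oracle agreement is meaningful.
"""

import numpy as np


def variogram_oracle(slice_, h, intensity_min, row_min):
    """Masked lag-h semi-variogram by explicit double loop over pixels.

    Pairs are (row, col) and (row, col + h) within the same row, rows
    >= row_min (1-based), both intensities >= intensity_min.
    Returns (gamma, n_pairs); gamma is NaN when n_pairs == 0.
    """
    a = np.asarray(slice_, dtype=float)
    total = 0.0
    n = 0
    for r in range(a.shape[0]):
        if r + 1 < row_min:
            continue
        for col in range(a.shape[1] - h):
            f1, f2 = a[r, col], a[r, col + h]
            if f1 >= intensity_min and f2 >= intensity_min:
                total += (f1 - f2) ** 2
                n += 1
    if n == 0:
        return float("nan"), 0
    return total / (2.0 * n), n


def maxmin_frp_oracle(U):
    """R(i, j) = max_k min(U[i, k], U[j, k]) by triple loop; unit diagonal."""
    U = np.asarray(U, dtype=float)
    L, c = U.shape
    R = np.zeros((L, L))
    for i in range(L):
        for j in range(L):
            if i == j:
                R[i, j] = 1.0
                continue
            best = 0.0
            for k in range(c):
                v = min(U[i, k], U[j, k])
                if v > best:
                    best = v
            R[i, j] = best
    return R


def maxmin_cluster_oracle(U, beta):
    """S(k, q) = max_i min(U'[i, k], U'[i, q]) with grades < beta floored."""
    U = np.asarray(U, dtype=float)
    U = np.where(U >= beta, U, 0.0)
    L, c = U.shape
    S = np.zeros((c, c))
    for k in range(c):
        for q in range(c):
            if k == q:
                S[k, q] = 1.0
                continue
            best = 0.0
            for i in range(L):
                v = min(U[i, k], U[i, q])
                if v > best:
                    best = v
            S[k, q] = best
    return S


def _scan_runs(values):
    """Lengths of maximal runs of ones in a 1-D sequence, by walking it."""
    runs = []
    current = 0
    for v in values:
        if v:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def run_histograms_oracle(B, exclude_loi=True):
    """(diagonal_counts, vertical_counts) by scanning every line explicitly."""
    B = np.asarray(B, dtype=bool)
    L = B.shape[0]
    n_d = max(L - 1, 1) if exclude_loi else L
    diag = np.zeros(n_d, dtype=int)
    for offset in range(-(L - 1), L):
        if exclude_loi and offset == 0:
            continue
        line = [B[i, i + offset] for i in range(max(0, -offset), min(L, L - offset))]
        for length in _scan_runs(line):
            diag[length - 1] += 1
    vert = np.zeros(L, dtype=int)
    for j in range(L):
        for length in _scan_runs(B[:, j]):
            vert[length - 1] += 1
    return diag, vert


def graph_metrics_oracle(A):
    """(characteristic path length, average clustering) by Floyd-Warshall and
    direct triangle counting."""
    A = np.asarray(A)
    n = A.shape[0]
    INF = float("inf")
    dist = [[0 if i == j else (1 if A[i][j] else INF) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    finite = [dist[i][j] for i in range(n) for j in range(n)
              if i != j and dist[i][j] < INF]
    cpl = sum(finite) / len(finite) if finite else 0.0

    total = 0.0
    for i in range(n):
        neigh = [j for j in range(n) if A[i][j]]
        d = len(neigh)
        if d < 2:
            continue
        links = sum(1 for a in range(d) for b in range(a + 1, d)
                    if A[neigh[a]][neigh[b]])
        total += 2.0 * links / (d * (d - 1))
    acc = total / n if n else 0.0
    return cpl, acc


def relu_convolve_oracle(M, kernel):
    """Valid-mode cross-correlation + ReLU by explicit quadruple loop."""
    M = np.asarray(M, dtype=float)
    K = np.asarray(kernel, dtype=float)
    kh, kw = K.shape
    oh, ow = M.shape[0] - kh + 1, M.shape[1] - kw + 1
    out = np.zeros((oh, ow))
    for i in range(oh):
        for j in range(ow):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    acc += M[i + a, j + b] * K[a, b]
            out[i, j] = acc if acc > 0 else 0.0
    return out


def max_pool_oracle(M, size, stride):
    """Max pooling with a truncated trailing window, by explicit loops."""
    M = np.asarray(M, dtype=float)

    def starts(n):
        s = list(range(0, n - size + 1, stride))
        last = s[-1] if s else 0
        if not s or last + size < n:
            nxt = last + stride if s else 0
            if nxt < n:
                s.append(nxt)
        return s

    rs, cs = starts(M.shape[0]), starts(M.shape[1])
    out = np.zeros((len(rs), len(cs)))
    for a, i in enumerate(rs):
        for b, j in enumerate(cs):
            best = -float("inf")
            for x in range(i, min(i + size, M.shape[0])):
                for y in range(j, min(j + size, M.shape[1])):
                    if M[x, y] > best:
                        best = M[x, y]
            out[a, b] = best
    return out


def eigen_reduce_oracle(M, kernel, pool_size, stride, final_size):
    """Full reduction schedule re-implemented from the naive pieces."""
    M = np.asarray(M, dtype=float)
    while M.shape[0] > final_size:
        M = relu_convolve_oracle(M, kernel)
        M = max_pool_oracle(M, pool_size, stride)
    return M


def autocorr(x, lag):
    """Sample autocorrelation at the given lag (Pearson r of x_t vs x_{t+lag})."""
    x = np.asarray(x, dtype=float)
    return float(np.corrcoef(x[:-lag], x[lag:])[0, 1])
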