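"""Independent brute-force oracles used only by the test suite."""
import math
import statistics


def pb_oracle(x, y):
    """Plain-loop Passing–Bablok estimate: enumerate every pairwise slope,
    apply the discard/offset rules longhand, and take the offset median.

    Returns (slope, intercept).  Kept free of numpy and of the library's
    vectorised implementation so agreement is a genuine cross-check.
    """
    slopes = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[j] - x[i]
            dy = y[j] - y[i]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                slopes.append(math.inf if dy > 0 else -math.inf)
                continue
            s = dy / dx
            if s == -1.0:
                continue
            slopes.append(s)
    slopes.sort()
    N = len(slopes)
    K = sum(1 for s in slopes if s < -1.0)
    if N % 2 == 1:
        b = slopes[(N - 1) // 2 + K]
    else:
        b = (slopes[N // 2 - 1 + K] + slopes[N // 2 + K]) / 2.0
    a = statistics.median(yi - b * xi for xi, yi in zip(x, y))
    return b, a


def two_pass_sd(values):
    """Textbook two-pass sample standard deviation."""
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
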