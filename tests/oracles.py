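"""Independent brute-force / closed-form oracles used by the tests.

Everything here is deliberately naive (explicit loops, textbook formulas) and
shares no code with the package implementation it checks.
"""

from __future__ import annotations

import numpy as np


def bilinear(img: np.ndarray, r: float, c: float) -> float:
    n, m = img.shape
    r = min(max(r, 0.0), n - 1.0)
    c = min(max(c, 0.0), m - 1.0)
    r0, c0 = min(int(np.floor(r)), n - 2), min(int(np.floor(c)), m - 2)
    dr, dc = r - r0, c - c0
    return float(
        img[r0, c0] * (1 - dr) * (1 - dc)
        + img[r0 + 1, c0] * dr * (1 - dc)
        + img[r0, c0 + 1] * (1 - dr) * dc
        + img[r0 + 1, c0 + 1] * dr * dc
    )


def brute_lbp_uniform(img: np.ndarray, P: int, R: int) -> np.ndarray:
    """Per-pixel rotation-invariant uniform LBP codes, interior pixels only.

    Neighbour p sits at (row - R sin(2 pi p / P), col + R cos(2 pi p / P)),
    sampled bilinearly; sign >= 0 against the centre; uniform patterns
    (<= 2 transitions) code to their number of ones, the rest to P + 1.
    """
    n, m = img.shape
    out = np.full((n, m), np.nan)
    for i in range(R, n - R):
        for j in range(R, m - R):
            s = []
            for p in range(P):
                ang = 2 * np.pi * p / P
                v = bilinear(img, i - R * np.sin(ang), j + R * np.cos(ang))
                s.append(1 if v - img[i, j] >= 0 else 0)
            trans = sum(s[k] != s[(k + 1) % P] for k in range(P))
            out[i, j] = sum(s) if trans <= 2 else P + 1
    return out


def brute_lpq_codes(img: np.ndarray, winsize: int = 7) -> np.ndarray:
    """LPQ code image by explicit windowed DFT sums (valid region)."""
    r = winsize // 2
    a = 1.0 / winsize
    freqs = [(0.0, a), (a, 0.0), (a, a), (a, -a)]  # (fy, fx) for u1..u4
    n, m = img.shape
    out = np.zeros((n - 2 * r, m - 2 * r), dtype=np.uint8)
    for i in range(r, n - r):
        for j in range(r, m - r):
            F = []
            for fy, fx in freqs:
                acc = 0.0 + 0.0j
                for dy in range(-r, r + 1):
                    for dx in range(-r, r + 1):
                        acc += img[i + dy, j + dx] * np.exp(
                            -2j * np.pi * (fy * dy + fx * dx)
                        )
                F.append(acc)
            g = [f.real for f in F] + [f.imag for f in F]
            code = 0
            for b, val in enumerate(g):
                if val > 1e-9:
                    code |= 1 << b
            out[i - r, j - r] = code
    return out


def brute_glcm_counts(q: np.ndarray, distance: int, angle_deg: float, levels: int) -> np.ndarray:
    """Co-occurrence counts by explicit pixel-pair tallying.

    Offset convention (matching the standard row/col definition):
    (drow, dcol) = (distance * sin(angle), distance * cos(angle)).
    """
    ang = np.deg2rad(angle_deg)
    drow = int(round(distance * np.sin(ang)))
    dcol = int(round(distance * np.cos(ang)))
    n, m = q.shape
    counts = np.zeros((levels, levels))
    for i in range(n):
        for j in range(m):
            i2, j2 = i + drow, j + dcol
            if 0 <= i2 < n and 0 <= j2 < m:
                counts[q[i, j], q[i2, j2]] += 1
    return counts


def welch_t_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Textbook Welch statistic with Welch-Satterthwaite df, two-sided p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = a.size, b.size
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * tdist.sf(abs(t), df)
    return float(t), float(p)


def auc_u_statistic(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the pairwise-comparison (Mann-Whitney U) probability."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (pos.size * neg.size)


def brute_youden(labels: np.ndarray, scores: np.ndarray) -> float:
    """Max over all thresholds of TPR - FPR, by direct enumeration."""
    best = -np.inf
    for thr in np.unique(scores):
        pred = scores >= thr
        tpr = pred[labels == 1].mean()
        fpr = pred[labels == 0].mean()
        best = max(best, tpr - fpr)
    return float(best)


def fourier_dominant_angle(img: np.ndarray, f_lo: float = 0.03, f_hi: float = 0.2) -> float:
    """Angle (deg, in [0, 180)) of maximal band-limited 2-D Fourier energy."""
    F = np.abs(np.fft.fft2(img - img.mean())) ** 2
    n = img.shape[0]
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    r = np.hypot(fx, fy)
    ang = np.rad2deg(np.arctan2(fy, fx)) % 180.0
    bins = np.arange(0, 181, 5)
    sel = (r > f_lo) & (r < f_hi)
    energy, _ = np.histogram(ang[sel], bins=bins, weights=F[sel])
    centers = (bins[:-1] + bins[1:]) / 2
    return float(centers[np.argmax(energy)])
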