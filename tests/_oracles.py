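"""Independent brute-force oracles used by the test suite.

Everything here is written per-definition with explicit loops and no shared
code with the package, so implementation and oracle can only agree if both
are right.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------- features

def _monotone_chain(points):
    """Convex hull (Andrew's monotone chain); returns hull vertices CCW."""
    pts = sorted(set(points))
    if len(pts) <= 2:
        return pts

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower, upper = [], []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    for p in reversed(pts):
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    return lower[:-1] + upper[:-1]


def _polygon_area(verts):
    area = 0.0
    for i in range(len(verts)):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % len(verts)]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def _np_gradient_2d(values):
    """Replicates numpy's gradient convention with explicit loops."""
    H, W = values.shape
    gy = np.zeros_like(values, dtype=float)
    gx = np.zeros_like(values, dtype=float)
    for r in range(H):
        for c in range(W):
            if 0 < r < H - 1:
                gy[r, c] = (values[r + 1, c] - values[r - 1, c]) / 2.0
            elif r == 0:
                gy[r, c] = values[1, c] - values[0, c]
            else:
                gy[r, c] = values[H - 1, c] - values[H - 2, c]
            if 0 < c < W - 1:
                gx[r, c] = (values[r, c + 1] - values[r, c - 1]) / 2.0
            elif c == 0:
                gx[r, c] = values[r, 1] - values[r, 0]
            else:
                gx[r, c] = values[r, W - 1] - values[r, W - 2]
    return gy, gx


def _gauss_smooth(values, sigma=1.0, truncate=3.0):
    """Zero-padded separable Gaussian smoothing with explicit sums."""
    radius = int(truncate * sigma + 0.5)
    w = np.array([math.exp(-0.5 * (i / sigma) ** 2)
                  for i in range(-radius, radius + 1)])
    w /= w.sum()
    H, W = values.shape
    tmp = np.zeros_like(values, dtype=float)
    out = np.zeros_like(values, dtype=float)
    for r in range(H):
        for c in range(W):
            acc = 0.0
            for k in range(-radius, radius + 1):
                if 0 <= c + k < W:
                    acc += w[k + radius] * values[r, c + k]
            tmp[r, c] = acc
    for r in range(H):
        for c in range(W):
            acc = 0.0
            for k in range(-radius, radius + 1):
                if 0 <= r + k < H:
                    acc += w[k + radius] * tmp[r + k, c]
            out[r, c] = acc
    return out


def oracle_features(values, mask, pixel_area):
    """All 24 features per definition.  Assumes the mask bbox sits close
    enough to the patch edges that the implementation's internal crop equals
    the full patch (true for the 9x9 / 11x11 constructions used in tests)."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    H, W = mask.shape
    pts = [(r, c) for r in range(H) for c in range(W) if mask[r, c]]
    n = len(pts)
    pa = pixel_area
    pitch = math.sqrt(pa)
    vals = [float(values[r, c]) for r, c in pts]

    out = {}
    out["area_um2"] = n * pa
    out["equivalent_diameter_um"] = 2.0 * math.sqrt(n * pa / math.pi)

    edges = 0
    for r, c in pts:
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < H and 0 <= cc < W) or not mask[rr, cc]:
                edges += 1
    out["perimeter_um"] = edges * pitch
    out["circularity"] = 4 * math.pi * n * pa / (edges * pitch) ** 2

    rbar = sum(r for r, _ in pts) / n
    cbar = sum(c for _, c in pts) / n
    mu20 = sum((r - rbar) ** 2 for r, _ in pts) / n
    mu02 = sum((c - cbar) ** 2 for _, c in pts) / n
    mu11 = sum((r - rbar) * (c - cbar) for r, c in pts) / n
    common = math.sqrt(((mu20 - mu02) / 2) ** 2 + mu11**2)
    lam1 = (mu20 + mu02) / 2 + common
    lam2 = max((mu20 + mu02) / 2 - common, 0.0)
    out["eccentricity"] = math.sqrt(1 - lam2 / lam1) if lam1 > 0 else 0.0
    major = 4 * math.sqrt(lam1) * pitch
    minor = 4 * math.sqrt(lam2) * pitch
    out["major_axis_um"] = major
    out["minor_axis_um"] = minor
    out["aspect_ratio"] = major / max(minor, pitch)

    corners = [(r + dr, c + dc) for r, c in pts
               for dr in (-0.5, 0.5) for dc in (-0.5, 0.5)]
    out["solidity"] = n / _polygon_area(_monotone_chain(corners))
    rmin = min(r for r, _ in pts); rmax = max(r for r, _ in pts)
    cmin = min(c for _, c in pts); cmax = max(c for _, c in pts)
    out["extent"] = n / ((rmax - rmin + 1) * (cmax - cmin + 1))

    mean = sum(vals) / n
    vmin, vmax = min(vals), max(vals)
    m2 = sum((v - mean) ** 2 for v in vals) / n
    sd = math.sqrt(m2)
    out["mean_phase"] = mean
    out["median_phase"] = float(np.median(vals))
    out["max_phase"] = vmax
    out["min_phase"] = vmin
    out["phase_range"] = vmax - vmin
    out["std_phase"] = sd
    if sd > 0:
        out["phase_skewness"] = (sum((v - mean) ** 3 for v in vals) / n) / m2**1.5
        out["phase_kurtosis"] = (sum((v - mean) ** 4 for v in vals) / n) / m2**2 - 3
    else:
        out["phase_skewness"] = 0.0
        out["phase_kurtosis"] = 0.0

    if vmax > vmin:
        counts = [0] * 32
        for v in vals:
            b = int((v - vmin) / (vmax - vmin) * 32)
            counts[min(b, 31)] += 1
        out["phase_entropy"] = -sum((k / n) * math.log(k / n)
                                    for k in counts if k > 0)
    else:
        out["phase_entropy"] = 0.0

    out["optical_volume"] = sum(vals) * pa

    wsum = sum(vals)
    if wsum > 0:
        wr = sum(r * values[r, c] for r, c in pts) / wsum
        wc = sum(c * values[r, c] for r, c in pts) / wsum
        out["mass_displacement_um"] = math.hypot(wr - rbar, wc - cbar) * pitch
    else:
        out["mass_displacement_um"] = 0.0

    gy, gx = _np_gradient_2d(values)
    out["mean_gradient_magnitude"] = sum(
        math.hypot(gy[r, c], gx[r, c]) for r, c in pts) / n

    rad = [math.hypot(r - rbar, c - cbar) for r, c in pts]
    rmaxd = max(rad)
    if rmaxd > 0:
        rings = {}
        for d, v in zip(rad, vals):
            k = min(int(d / rmaxd * 4), 3)
            rings.setdefault(k, []).append(v)
        means = [sum(vs) / len(vs) for _, vs in sorted(rings.items())]
        mm = sum(means) / len(means)
        out["radial_contrast"] = math.sqrt(
            sum((m - mm) ** 2 for m in means) / len(means))
    else:
        out["radial_contrast"] = 0.0

    sm = _gauss_smooth(values)
    count = 0
    for r, c in pts:
        is_max = True
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                nb = sm[rr, cc] if 0 <= rr < H and 0 <= cc < W else -math.inf
                if sm[r, c] <= nb:
                    is_max = False
        count += is_max
    out["local_maxima_count"] = float(count)
    return out


# ------------------------------------------------- connected components

def flood_components(grid, connectivity):
    """Exhaustive BFS flood fill; returns a set of frozensets of coords."""
    grid = np.asarray(grid, dtype=bool)
    H, W = grid.shape
    if connectivity == 4:
        nbrs = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    seen = np.zeros_like(grid)
    comps = set()
    for r in range(H):
        for c in range(W):
            if grid[r, c] and not seen[r, c]:
                stack = [(r, c)]
                seen[r, c] = True
                comp = []
                while stack:
                    cr, cc = stack.pop()
                    comp.append((cr, cc))
                    for dr, dc in nbrs:
                        nr, nc = cr + dr, cc + dc
                        if (0 <= nr < H and 0 <= nc < W and grid[nr, nc]
                                and not seen[nr, nc]):
                            seen[nr, nc] = True
                            stack.append((nr, nc))
                comps.add(frozenset(comp))
    return comps


# ------------------------------------------------------------- metrics

def oracle_metrics(counts):
    """Accuracy / per-class sensitivity & specificity from first principles."""
    counts = np.asarray(counts)
    C = counts.shape[0]
    total = int(counts.sum())
    acc = sum(int(counts[i, i]) for i in range(C)) / total
    sens, spec = [], []
    for i in range(C):
        tp = int(counts[i, i])
        fn = int(counts[i].sum()) - tp
        fp = int(counts[:, i].sum()) - tp
        tn = total - tp - fn - fp
        sens.append(tp / (tp + fn) if tp + fn > 0 else float("nan"))
        spec.append(tn / (tn + fp) if tn + fp > 0 else float("nan"))
    return acc, sens, spec
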