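"""Shared fixtures: constructed geometries, an independent brute-force
contact classifier, and session-scoped synthetic datasets reused across
test modules to keep the suite fast."""

from __future__ import annotations

import math

import numpy as np
import pytest

from myomam.contours import Contour, MitochondrionProfile
from myomam.morphometry import summarize_fieldset
from myomam.simulate_prot import ProteomeSimConfig, simulate_proteome
from myomam.simulate_ultra import make_preset, simulate_fieldset


def circle_polygon(radius: float, n: int = 720, center=(0.0, 0.0)) -> np.ndarray:
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(t), center[1] + radius * np.sin(t)]
    )


def concentric_arc(
    radius: float, gap: float, frac: float, n: int = 400, start_angle: float = 0.0,
    center=(0.0, 0.0),
) -> np.ndarray:
    """Open arc at radius+gap spanning ``frac`` of the circle."""
    t = start_angle + np.linspace(0, 2 * math.pi * frac, n)
    r = radius + gap
    return np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])


def mito_profile(vertices, cristae=(), mito_id="m1", field_id="f1"):
    return MitochondrionProfile(
        outline=Contour(vertices, closed=True, label="mitochondrion", id=mito_id),
        cristae=[
            Contour(c, closed=False, label="crista", id=f"c{i}", parent_mito=mito_id)
            for i, c in enumerate(cristae)
        ],
        id=mito_id,
        field_id=field_id,
    )


def er_contour(vertices, er_id="e1"):
    return Contour(vertices, closed=False, label="er", id=er_id)


# ---------------------------------------------------------------------------
# independent brute-force contact classifier (numpy only, no shapely)
# ---------------------------------------------------------------------------

def _point_segment_dist(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Min distance from each point to each segment [a_i, b_i]; (P, S)."""
    ab = b - a  # (S, 2)
    ap = pts[:, None, :] - a[None, :, :]  # (P, S, 2)
    denom = np.einsum("sd,sd->s", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.clip(np.einsum("psd,sd->ps", ap, ab) / denom, 0.0, 1.0)
    closest = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    return np.linalg.norm(pts[:, None, :] - closest, axis=2)


def brute_force_segments(
    outline: np.ndarray,
    er_traces: list[np.ndarray],
    band=(10.0, 30.0),
    step: float = 0.1,
    min_length: float = 10.0,
    merge_gap: float = 5.0,
) -> list[tuple[float, float]]:
    """Dense-sampling oracle: classify 0.1 nm boundary samples and extract
    (arc_start, arc_end) contact intervals, duplicating the published rules
    (gap band, merge, minimum length, split at the origin) independently."""
    closed = np.vstack([outline, outline[:1]])
    seg_len = np.hypot(*np.diff(closed, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    perimeter = cum[-1]
    n = int(math.ceil(perimeter / step))
    s = np.arange(n) * (perimeter / n)
    pts = np.column_stack(
        [np.interp(s, cum, closed[:, 0]), np.interp(s, cum, closed[:, 1])]
    )
    dmin = np.full(n, np.inf)
    for trace in er_traces:
        a, b = trace[:-1], trace[1:]
        # chunk to bound memory
        for lo in range(0, n, 20000):
            d = _point_segment_dist(pts[lo:lo + 20000], a, b).min(axis=1)
            dmin[lo:lo + 20000] = np.minimum(dmin[lo:lo + 20000], d)
    mask = (dmin >= band[0]) & (dmin <= band[1])
    if not mask.any():
        return []
    spacing = perimeter / n
    # circular runs
    if mask.all():
        return [(0.0, perimeter)]
    off = int(np.argmin(mask))
    rot = np.roll(mask, -off)
    padded = np.concatenate([[False], rot, [False]])
    diff = np.diff(padded.astype(int))
    starts = [(int(i) + off) % n for i in np.nonzero(diff == 1)[0]]
    counts = [int(e - b0) for b0, e in zip(np.nonzero(diff == 1)[0],
                                           np.nonzero(diff == -1)[0])]
    runs = sorted(zip(starts, counts))
    # merge short circular gaps
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for i in range(len(runs)):
            st, ct = runs[i]
            nst, nct = runs[(i + 1) % len(runs)]
            gap = (nst - (st + ct)) % n
            if 0 < gap * spacing < merge_gap:
                if (i + 1) % len(runs) == i:
                    break
                merged = (st, ct + gap + nct)
                rest = [runs[j] for j in range(len(runs))
                        if j not in (i, (i + 1) % len(runs))]
                runs = sorted(rest + [merged])
                changed = True
                break
    out = []
    for st, ct in runs:
        if ct * spacing < min_length:
            continue
        start_s = s[st % n]
        end_s = start_s + ct * spacing
        if end_s <= perimeter + 1e-9:
            out.append((start_s, min(end_s, perimeter)))
        else:
            out.append((start_s, perimeter))
            out.append((0.0, end_s - perimeter))
    return sorted(out)


# ---------------------------------------------------------------------------
# session-scoped synthetic datasets
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def young_fieldset():
    """Young-heart synthetic fields with truth and measured records."""
    fields, truth = simulate_fieldset(make_preset("heart", "young"), 80, seed=11)
    records, segments = summarize_fieldset(fields, age_group="young", tissue="heart")
    return fields, truth, records, segments


@pytest.fixture(scope="session")
def proteome_sim():
    """Default synthetic proteome (seed 7) shared across proteomics tests."""
    return simulate_proteome(ProteomeSimConfig(seed=7))
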