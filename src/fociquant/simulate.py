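"""Synthetic three-channel fields with known ground truth.

Emulates high-content acquisition of irradiated, immunostained cells:
non-overlapping elliptical nuclei (blue, smooth DAPI-like profile), foci of
the DSB marker as 2-D Gaussian puncta inside nuclei (green), and DDR-protein
foci (red) of which a controllable fraction φ sits exactly at green focus
centers (co-localized) while the rest land at independent positions.  Each
nucleus draws its own staining background per channel, reproducing the
between-cell background variation that motivates per-nucleus thresholding.
Shot (Poisson) noise and Gaussian read noise are applied last.  Everything
is reproducible from the seed.

A co-localized red focus inherits its green partner's center, sigma and
amplitude (the amplitude scaled by the ratio of the red/green amplitude
range midpoints), so that with φ = 1, equal amplitude ranges, equal
backgrounds and no noise the red channel reproduces the green channel
exactly and the pipeline's co-localization ratio is 1 by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology as skmorph

from .exceptions import PlacementError
from .io import FieldImage

Range = Tuple[float, float]


def _check_range(name: str, rng_: Range, lo_ok: float = 0.0) -> None:
    lo, hi = rng_
    if not (lo_ok <= lo <= hi):
        raise ValueError(f"{name}: invalid range {rng_}")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic field.

    Ranges are inclusive ``(low, high)``; a fixed value is ``(v, v)``.
    Intensities are in camera counts of the output bit depth.
    """

    shape: Tuple[int, int] = (512, 512)
    n_nuclei: int = 12
    nucleus_axes: Range = (14.0, 26.0)  # semi-axes, px
    nucleus_brightness: Range = (20000.0, 40000.0)  # blue channel, counts
    background: Range = (300.0, 600.0)  # per-nucleus foci-channel background
    foci_per_nucleus: Tuple[int, int] = (5, 12)
    focus_sigma: Range = (1.5, 2.5)  # px
    focus_amplitude: Range = (5000.0, 9000.0)  # green peak height above background
    red_amplitude: Optional[Range] = None  # defaults to focus_amplitude
    coloc_fraction: float = 0.5  # φ: fraction of red foci at green centers
    min_separation_px: float = 0.0  # min distance between focus centers in a nucleus
    poisson_noise: bool = True
    read_noise_sd: float = 10.0
    bit_depth: int = 16
    seed: int = 0
    max_place_tries: int = 200  # placement attempts per nucleus

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        _check_range("nucleus_axes", self.nucleus_axes, lo_ok=1.0)
        _check_range("nucleus_brightness", self.nucleus_brightness)
        _check_range("background", self.background)
        _check_range("focus_sigma", self.focus_sigma, lo_ok=0.3)
        _check_range("focus_amplitude", self.focus_amplitude)
        if self.red_amplitude is not None:
            _check_range("red_amplitude", self.red_amplitude)
        if self.foci_per_nucleus[0] < 0 or self.foci_per_nucleus[0] > self.foci_per_nucleus[1]:
            raise ValueError("invalid foci_per_nucleus range")
        maxval = 2**self.bit_depth - 1
        for name in ("nucleus_brightness", "background", "focus_amplitude"):
            if getattr(self, name)[1] > maxval:
                raise ValueError(f"{name} exceeds bit depth maximum {maxval}")

    @property
    def dtype(self):
        return np.uint8 if self.bit_depth == 8 else np.uint16


@dataclass
class FocusTruth:
    """One ground-truth focus."""

    nucleus_id: int
    channel: str  # "green" | "red"
    center: Tuple[float, float]  # (row, col)
    sigma: float
    amplitude: float
    colocalized: bool = False


@dataclass
class GroundTruth:
    """Everything the generator knows about a scene."""

    masks: List[np.ndarray]
    foci: List[FocusTruth]
    coloc_fraction: Dict[int, float]  # true per-nucleus red coloc fraction
    true_signal: Dict[Tuple[int, str], float]  # rendered focus signal per nucleus/channel

    def foci_of(self, nucleus_id: int, channel: str) -> List[FocusTruth]:
        return [f for f in self.foci if f.nucleus_id == nucleus_id and f.channel == channel]


def _ellipse_mask(shape, center, axes, angle) -> np.ndarray:
    cy, cx = center
    a, b = axes
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = rr - cy, cc - cx
    ca, sa = math.cos(angle), math.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_nuclei(spec: SceneSpec, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipses, fully inside the field."""
    h, w = spec.shape
    masks, params = [], []
    occupied = np.zeros(spec.shape, dtype=bool)
    gap = 3.0  # px of clearance so neighboring nuclei never merge
    for i in range(spec.n_nuclei):
        placed = False
        for _ in range(spec.max_place_tries):
            a = rng.uniform(*spec.nucleus_axes)
            b = rng.uniform(*spec.nucleus_axes)
            margin = max(a, b) + gap
            if 2 * margin >= min(h, w):
                continue
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            angle = rng.uniform(0, math.pi)
            inflated = _ellipse_mask(spec.shape, (cy, cx), (a + gap, b + gap), angle)
            if (inflated & occupied).any():
                continue
            mask = _ellipse_mask(spec.shape, (cy, cx), (a, b), angle)
            occupied |= inflated
            masks.append(mask)
            params.append(((cy, cx), (a, b), angle))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{spec.n_nuclei} without overlap; "
                "reduce n_nuclei or nucleus_axes"
            )
    return masks, params


def _sample_focus_centers(
    mask: np.ndarray, n: int, min_sep: float, rng: np.random.Generator
) -> List[Tuple[int, int]]:
    interior = ndi.binary_erosion(mask, skmorph.disk(2), border_value=0)
    if not interior.any():
        interior = mask
    coords = np.transpose(np.nonzero(interior))
    centers: List[Tuple[int, int]] = []
    for _ in range(n):
        for _try in range(50):
            r, c = coords[rng.integers(len(coords))]
            if min_sep <= 0 or all(
                math.hypot(r - r0, c - c0) >= min_sep for r0, c0 in centers
            ):
                centers.append((int(r), int(c)))
                break
        # after 50 failed tries the focus is skipped (truth records what exists)
    return centers


def _render_focus(
    canvas: np.ndarray, mask: np.ndarray, center, sigma: float, amplitude: float
) -> float:
    """Add a mask-confined Gaussian punctum; returns the signal actually added."""
    h, w = canvas.shape
    r0c, c0c = center
    rad = int(math.ceil(4 * sigma))
    r0, r1 = max(0, r0c - rad), min(h, r0c + rad + 1)
    c0, c1 = max(0, c0c - rad), min(w, c0c + rad + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    patch = amplitude * np.exp(-((rr - r0c) ** 2 + (cc - c0c) ** 2) / (2 * sigma**2))
    patch *= mask[r0:r1, c0:c1]
    canvas[r0:r1, c0:c1] += patch
    return float(patch.sum())


def generate_scene(spec: SceneSpec) -> Tuple[FieldImage, GroundTruth]:
    """Generate one three-channel field and its ground truth.

    Raises :class:`PlacementError` if ``n_nuclei`` ellipses cannot be placed
    without overlap within the bounded retry budget.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    blue = np.zeros(spec.shape, dtype=np.float64)
    green = np.zeros(spec.shape, dtype=np.float64)
    red = np.zeros(spec.shape, dtype=np.float64)

    masks, params = _place_nuclei(spec, rng) if spec.n_nuclei else ([], [])

    foci: List[FocusTruth] = []
    coloc_frac: Dict[int, float] = {}
    true_signal: Dict[Tuple[int, str], float] = {}
    red_amp_range = spec.red_amplitude or spec.focus_amplitude
    green_mid = (spec.focus_amplitude[0] + spec.focus_amplitude[1]) / 2
    red_mid = (red_amp_range[0] + red_amp_range[1]) / 2
    amp_scale = red_mid / green_mid if green_mid > 0 else 1.0

    for nid, (mask, ((cy, cx), (a, b), angle)) in enumerate(zip(masks, params)):
        # blue: domed DAPI-like profile, brighter toward the nucleus center
        ca, sa = math.cos(angle), math.sin(angle)
        rr, cc = np.nonzero(mask)
        dx, dy = cc - cx, rr - cy
        u = dx * ca + dy * sa
        v = -dx * sa + dy * ca
        rho2 = (u / a) ** 2 + (v / b) ** 2
        level = rng.uniform(*spec.nucleus_brightness)
        blue[rr, cc] += level * (1.0 - 0.3 * rho2)

        # per-cell staining background in the foci channels
        bg_green = rng.uniform(*spec.background)
        bg_red = rng.uniform(*spec.background)
        green[mask] += bg_green
        red[mask] += bg_red

        # green foci
        n_green = int(rng.integers(spec.foci_per_nucleus[0], spec.foci_per_nucleus[1] + 1))
        centers = _sample_focus_centers(mask, n_green, spec.min_separation_px, rng)
        sig_g = 0.0
        green_list: List[FocusTruth] = []
        for ctr in centers:
            sigma = rng.uniform(*spec.focus_sigma)
            amp = rng.uniform(*spec.focus_amplitude)
            sig_g += _render_focus(green, mask, ctr, sigma, amp)
            green_list.append(FocusTruth(nid, "green", ctr, sigma, amp))
        foci.extend(green_list)
        true_signal[(nid, "green")] = sig_g

        # red foci: a fraction φ of green foci receive a co-localized red
        # partner; independent red foci scale with 1 − φ, so φ = 1 copies the
        # green foci exactly and φ = 0 is fully independent
        n_red = int(rng.integers(spec.foci_per_nucleus[0], spec.foci_per_nucleus[1] + 1))
        n_coloc = int(round(spec.coloc_fraction * len(green_list)))
        partners = (
            rng.choice(len(green_list), size=n_coloc, replace=False) if n_coloc else []
        )
        sig_r = 0.0
        placed_red = 0
        for j in partners:
            g = green_list[int(j)]
            amp = g.amplitude * amp_scale
            sig_r += _render_focus(red, mask, g.center, g.sigma, amp)
            foci.append(FocusTruth(nid, "red", g.center, g.sigma, amp, colocalized=True))
            placed_red += 1
        n_indep = int(round((1.0 - spec.coloc_fraction) * n_red))
        for ctr in _sample_focus_centers(mask, n_indep, spec.min_separation_px, rng):
            sigma = rng.uniform(*spec.focus_sigma)
            amp = rng.uniform(*red_amp_range)
            sig_r += _render_focus(red, mask, ctr, sigma, amp)
            foci.append(FocusTruth(nid, "red", ctr, sigma, amp, colocalized=False))
            placed_red += 1
        true_signal[(nid, "red")] = sig_r
        coloc_frac[nid] = n_coloc / placed_red if placed_red else math.nan

    maxval = 2**spec.bit_depth - 1
    channels = {}
    for name, img in (("blue", blue), ("green", green), ("red", red)):
        out = img
        if spec.poisson_noise:
            out = rng.poisson(np.clip(out, 0, None)).astype(np.float64)
        if spec.read_noise_sd > 0:
            out = out + rng.normal(0.0, spec.read_noise_sd, size=out.shape)
        channels[name] = np.clip(np.rint(out), 0, maxval).astype(spec.dtype)

    field = FieldImage(field_id=f"sim{spec.seed}", well_id="simw", **channels)
    truth = GroundTruth(
        masks=masks, foci=foci, coloc_fraction=coloc_frac, true_signal=true_signal
    )
    return field, truth


def sparse_spec(seed: int = 0, **overrides) -> SceneSpec:
    """Well-separated, high-SNR foci: the easy recovery regime.

    Amplitude/background >= 10 and focus centers at least 12 px apart, so a
    correct pipeline should recover essentially every focus.
    """
    base = SceneSpec(
        shape=(384, 384),
        n_nuclei=8,
        nucleus_axes=(14.0, 22.0),
        foci_per_nucleus=(4, 8),
        focus_sigma=(1.5, 2.0),
        focus_amplitude=(6000.0, 9000.0),
        background=(300.0, 550.0),
        min_separation_px=12.0,
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base


def dense_spec(seed: int = 0, **overrides) -> SceneSpec:
    """Dense, overlapping foci: the regime where counting breaks down.

    Mean nearest-neighbor distance between focus centers is below 2 sigma,
    so puncta merge into conglomerates; counting undercounts while
    integrated intensity, being additive, stays accurate.
    """
    base = SceneSpec(
        shape=(512, 512),
        n_nuclei=5,
        nucleus_axes=(26.0, 36.0),
        foci_per_nucleus=(60, 80),
        focus_sigma=(2.0, 2.0),
        focus_amplitude=(10000.0, 14000.0),
        background=(150.0, 250.0),
        min_separation_px=0.0,
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass
class NucleusRecovery:
    """Detected-vs-true foci bookkeeping for one matched nucleus."""

    nucleus_id: int  # detected id
    true_id: int
    true_count: int
    detected_count: int
    matched_centers: int  # true centers inside detected support
    true_positive_components: int  # detected components containing a true center


@dataclass
class RecoveryReport:
    """Scene-level detection recovery against ground truth.

    ``recall`` pools true centers over all matched nuclei; ``precision``
    pools detected components.  Both are NaN when vacuous (nothing to
    match), which is not an error.
    """

    per_nucleus: List[NucleusRecovery]
    recall: float
    precision: float
    n_unmatched_detected: int
    n_unmatched_true: int

    @property
    def mean_true_count(self) -> float:
        return (
            float(np.mean([r.true_count for r in self.per_nucleus]))
            if self.per_nucleus
            else math.nan
        )

    @property
    def mean_detected_count(self) -> float:
        return (
            float(np.mean([r.detected_count for r in self.per_nucleus]))
            if self.per_nucleus
            else math.nan
        )


def truth_match(
    processed: Sequence,
    truth: GroundTruth,
    channel: str = "green",
    tolerance: int = 0,
    connectivity: int = 8,
    min_focus_px: int = 4,
) -> RecoveryReport:
    """Score detected foci against ground truth by center containment.

    ``processed`` is a sequence of pipeline results, each carrying a
    ``record`` (NucleusRecord) and ``green_foci`` / ``red_foci``
    (FociImage).  Detected nuclei are matched to true masks by maximum
    pixel overlap; a true focus is recovered when its center falls inside
    the (optionally ``tolerance``-dilated) size-filtered detected support,
    and a detected component is a true positive when it contains at least
    one true center.
    """
    from .measure import _filtered_support  # local import avoids cycle at module load

    matched: List[NucleusRecovery] = []
    used_true = set()
    n_unmatched_detected = 0
    total_true = total_matched = total_comps = total_tp = 0

    for proc in processed:
        record = proc.record
        overlaps = [int(np.count_nonzero(record.mask & tm)) for tm in truth.masks]
        if not overlaps or max(overlaps) == 0:
            n_unmatched_detected += 1
            continue
        true_id = int(np.argmax(overlaps))
        used_true.add(true_id)
        foci_img = proc.green_foci if channel == "green" else proc.red_foci
        labels, kept = _filtered_support(foci_img, connectivity, min_focus_px)
        kept_set = set(kept)
        r0, _, c0, _ = record.bbox
        h_loc, w_loc = labels.shape

        # a center "hits" every kept component within `tolerance` pixels of it
        centers = [f.center for f in truth.foci_of(true_id, channel)]
        n_matched = 0
        hit_labels = set()
        for r, c in centers:
            lr, lc = int(round(r)) - r0, int(round(c)) - c0
            win = labels[
                max(0, lr - tolerance) : min(h_loc, lr + tolerance + 1),
                max(0, lc - tolerance) : min(w_loc, lc + tolerance + 1),
            ]
            here = kept_set.intersection(np.unique(win).tolist())
            if here:
                n_matched += 1
                hit_labels |= here
        tp_components = len(hit_labels)
        matched.append(
            NucleusRecovery(
                nucleus_id=record.nucleus_id,
                true_id=true_id,
                true_count=len(centers),
                detected_count=len(kept),
                matched_centers=n_matched,
                true_positive_components=tp_components,
            )
        )
        total_true += len(centers)
        total_matched += n_matched
        total_comps += len(kept)
        total_tp += tp_components

    recall = total_matched / total_true if total_true else math.nan
    precision = total_tp / total_comps if total_comps else math.nan
    return RecoveryReport(
        per_nucleus=matched,
        recall=recall,
        precision=precision,
        n_unmatched_detected=n_unmatched_detected,
        n_unmatched_true=len(truth.masks) - len(used_true),
    )
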