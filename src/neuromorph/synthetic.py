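"""Synthetic EvG-like nerve cross-sections with exact ground truth.

The generator emulates the study cohort this package is designed around:
12 samples in three groups (4 control nerves, 3 non-painful neuromas with
NRS 0, 5 painful neuromas with NRS scores [5, 6, 7, 8, 8] — median 7,
range 5-8), each sample an RGB image of a nerve cross-section plus a
pixel-exact truth mask.

A rendered section consists of an elliptical nerve profile filled with
connective tissue, into which the generator packs:

* organized fascicles — near-round ellipses (axis ratio >= 0.78), whose
  rasterized circularity is verified >= 0.7;
* unorganized (neuroma) tissue — jagged star polygons with verified
  circularity <= 0.5, standing in for mini-fascicle clusters;
* adipose vacuoles (white circles) and erythrocyte specks (small red
  circles);

with an off-white slide background outside the nerve.  Painful samples get
a lower fraction of organized nervous tissue, scaled inversely with NRS, so
the downstream statistics have a known negative organized-vs-pain effect to
recover.  Colors follow the invented EvG-like palette in
:mod:`neuromorph.tissue`; per-component color jitter, a low-frequency
illumination gradient, mild smooth texture and i.i.d. Gaussian pixel noise
make the classification task non-trivial but learnable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.ndimage import gaussian_filter
from skimage import draw
from skimage.morphology import flood

from .io import CohortRecord, write_cohort_table, write_image, write_mask
from .morphometry import component_roundness
from .tissue import GROUPS, PALETTE, TissueClass

__all__ = [
    "CohortSpec",
    "GroundTruthSample",
    "PackingError",
    "default_cohort_spec",
    "null_cohort_spec",
    "build_records",
    "render_sample",
    "iter_samples",
    "generate_cohort",
]


class PackingError(RuntimeError):
    """Raised when a tissue class cannot be packed into the canvas."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``organized_fraction_by_group`` gives, per group, the target fraction of
    nervous-tissue pixels that belong to organized fascicles.  For painful
    samples, ``painful_nrs_scaling = (hi, lo)`` replaces the flat target by a
    linear ramp from ``hi`` at the lowest painful NRS to ``lo`` at the
    highest (set to ``None`` for a flat, NRS-independent target — the "null"
    configuration used for calibration runs).
    """

    n_control: int = 4
    n_nonpainful: int = 3
    n_painful: int = 5
    painful_nrs: tuple[int, ...] = (5, 6, 7, 8, 8)
    image_size: int = 512
    mpp: float = 0.5
    organized_fraction_by_group: dict[str, float] = field(
        default_factory=lambda: {
            "control": 0.95,
            "nonpainful_neuroma": 0.60,
            "painful_neuroma": 0.20,
        }
    )
    painful_nrs_scaling: tuple[float, float] | None = (0.30, 0.10)
    nervous_fraction: float = 0.40
    adipose_fraction_by_group: dict[str, float] = field(
        default_factory=lambda: {
            "control": 0.15,
            "nonpainful_neuroma": 0.10,
            "painful_neuroma": 0.08,
        }
    )
    erythrocyte_fraction: float = 0.015
    noise_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.painful_nrs) != self.n_painful:
            raise ValueError(
                f"painful_nrs has {len(self.painful_nrs)} entries for "
                f"{self.n_painful} painful samples"
            )
        if any(not (0 <= s <= 10) for s in self.painful_nrs):
            raise ValueError("every NRS must be within 0-10")
        if self.image_size < 256:
            raise ValueError("image_size must be >= 256")
        if not self.mpp > 0:
            raise ValueError("mpp must be > 0")
        for g, f in self.organized_fraction_by_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"organized fraction for {g!r} outside [0,1]")

    @property
    def n_total(self) -> int:
        return self.n_control + self.n_nonpainful + self.n_painful

    def organized_target(self, record: CohortRecord) -> float:
        """Target organized fraction of nervous pixels for one sample."""
        if (
            record.group == "painful_neuroma"
            and self.painful_nrs_scaling is not None
        ):
            hi, lo = self.painful_nrs_scaling
            nrs_lo, nrs_hi = min(self.painful_nrs), max(self.painful_nrs)
            if nrs_hi == nrs_lo:
                return 0.5 * (hi + lo)
            t = (record.nrs - nrs_lo) / (nrs_hi - nrs_lo)
            return hi + (lo - hi) * t
        return self.organized_fraction_by_group[record.group]


@dataclass(frozen=True)
class GroundTruthSample:
    """A rendered image with its exact truth mask and metadata."""

    image: np.ndarray
    truth_mask: np.ndarray
    record: CohortRecord
    rendered_fractions: dict[str, float]

    @property
    def organized_fraction_of_nervous(self) -> float:
        org = self.rendered_fractions["organized_nervous"]
        unorg = self.rendered_fractions["unorganized_nervous"]
        total = org + unorg
        return org / total if total > 0 else float("nan")


def default_cohort_spec(**overrides) -> CohortSpec:
    """The cohort the package emulates by default: 12 samples.

    4 controls and 3 non-painful neuromas with NRS 0, and 5 painful neuromas
    with NRS [5, 6, 7, 8, 8] (median 7, range 5-8) whose organized-tissue
    fraction ramps down with NRS.
    """
    return CohortSpec(**overrides)


def null_cohort_spec(**overrides) -> CohortSpec:
    """A calibration cohort whose organized fraction is independent of NRS.

    All groups share a flat 0.5 organized-fraction target, so any apparent
    organized-vs-pain correlation is pure placement noise.  Used for type-I
    error calibration of the statistics stage.
    """
    base = dict(
        organized_fraction_by_group={g: 0.5 for g in GROUPS},
        painful_nrs_scaling=None,
    )
    base.update(overrides)
    return CohortSpec(**base)


# ---------------------------------------------------------------------------
# Cohort records
# ---------------------------------------------------------------------------

# Sex patterns mirror the emulated cohort (painful 4M/1F, non-painful all
# male, controls 2M/2F); ages are drawn uniformly from each group's printed
# range and are uninformative about pain by construction.
_GROUP_META = {
    "control": dict(prefix="C", ages=(25, 77), sexes=("male", "male", "female", "female")),
    "nonpainful_neuroma": dict(prefix="N", ages=(38, 55), sexes=("male",) * 3),
    "painful_neuroma": dict(prefix="P", ages=(23, 61), sexes=("male", "male", "male", "male", "female")),
}


def build_records(spec: CohortSpec) -> list[CohortRecord]:
    """Deterministically build the cohort metadata table for a spec."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0]))
    records = []
    counts = {
        "control": spec.n_control,
        "nonpainful_neuroma": spec.n_nonpainful,
        "painful_neuroma": spec.n_painful,
    }
    for group in GROUPS:
        meta = _GROUP_META[group]
        lo, hi = meta["ages"]
        for i in range(counts[group]):
            nrs = spec.painful_nrs[i] if group == "painful_neuroma" else 0
            sexes = meta["sexes"]
            records.append(
                CohortRecord(
                    sample_id=f"{meta['prefix']}{i + 1:02d}",
                    group=group,
                    nrs=int(nrs),
                    age=float(rng.integers(lo, hi + 1)),
                    sex=sexes[i % len(sexes)],
                    mpp=spec.mpp,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _star_polygon(
    rng: np.random.Generator, center: tuple[float, float], radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vertex rows/cols of a jagged star polygon (low circularity)."""
    k = int(rng.integers(7, 12))  # spikes
    angles = np.linspace(0.0, 2 * np.pi, 2 * k, endpoint=False)
    angles = angles + rng.uniform(0, np.pi / k)
    inner = rng.uniform(0.40, 0.55)
    radii = np.where(np.arange(2 * k) % 2 == 0, 1.0, inner) * radius
    radii = radii * rng.uniform(0.90, 1.10, size=2 * k)
    return center[0] + radii * np.sin(angles), center[1] + radii * np.cos(angles)


class _Packer:
    """Distance-transform-guided placement inside the nerve profile.

    Two blocking masks enforce the separation rules: ``blocked_all`` is
    checked by organized/adipose/erythrocyte candidates (every placed
    component plus margins), while ``blocked_for_unorg`` omits unorganized
    footprints — neuroma blobs may overlap each other and merge into larger
    irregular clusters, they only keep a margin against other classes.
    Candidate centers are drawn from pixels whose free-space Euclidean
    distance transform exceeds the component's bounding radius, so the
    acceptance rate stays high even in a crowded section; the EDT is
    refreshed lazily and every candidate is still verified pixel-exactly.
    """

    def __init__(self, rng, nerve_core, shape):
        self.rng = rng
        self.core = nerve_core
        self.blocked_all = np.zeros(shape, dtype=bool)
        self.blocked_for_unorg = np.zeros(shape, dtype=bool)
        self.shape = shape

    def candidate_centers(self, bound_radius: float, blocked) -> np.ndarray:
        edt = ndimage.distance_transform_edt(self.core & ~blocked)
        return np.argwhere(edt > bound_radius + 0.5)

    def fits(self, rr, cc, blocked):
        if rr.size == 0:
            return False
        if (
            rr.min() < 0 or cc.min() < 0
            or rr.max() >= self.shape[0] or cc.max() >= self.shape[1]
        ):
            return False
        if not self.core[rr, cc].all():
            return False
        if blocked[rr, cc].any():
            return False
        return True

    def stamp(self, rr, cc, margin: int, unorganized: bool):
        """Record a placed component (footprint + margin) in the blockers."""
        targets = [self.blocked_all]
        if not unorganized:
            targets.append(self.blocked_for_unorg)
        for dr in range(-margin, margin + 1):
            for dc in range(-margin, margin + 1):
                r2 = np.clip(rr + dr, 0, self.shape[0] - 1)
                c2 = np.clip(cc + dc, 0, self.shape[1] - 1)
                for t in targets:
                    t[r2, c2] = True


def render_sample(
    spec: CohortSpec, record: CohortRecord, rng_seed: int
) -> GroundTruthSample:
    """Render one nerve cross-section and its exact truth mask.

    Deterministic in ``(spec, record, rng_seed)``.  The achieved organized
    fraction of nervous pixels is guaranteed within +-0.1 of the group
    target; failure to pack any class raises :class:`PackingError` naming it.
    """
    s = spec.image_size
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 0x51]))
    mask = np.zeros((s, s), dtype=np.uint8)

    # nerve profile: large rotated ellipse filled with connective tissue
    a = s * rng.uniform(0.38, 0.44)
    b = s * rng.uniform(0.38, 0.44)
    theta = rng.uniform(0, np.pi)
    cy, cx = (s / 2 + rng.uniform(-0.02, 0.02, 2) * s)
    rr, cc = draw.ellipse(cy, cx, a, b, shape=(s, s), rotation=theta)
    mask[rr, cc] = TissueClass.CONNECTIVE
    nerve = mask == TissueClass.CONNECTIVE
    rr, cc = draw.ellipse(cy, cx, a - 3, b - 3, shape=(s, s), rotation=theta)
    nerve_core = np.zeros((s, s), dtype=bool)
    nerve_core[rr, cc] = True
    n_nerve = int(nerve.sum())

    f_org = spec.organized_target(record)
    budgets = {
        TissueClass.ORGANIZED_NERVOUS: f_org * spec.nervous_fraction * n_nerve,
        TissueClass.UNORGANIZED_NERVOUS: (1 - f_org) * spec.nervous_fraction * n_nerve,
        TissueClass.ADIPOSE: spec.adipose_fraction_by_group[record.group] * n_nerve,
        TissueClass.ERYTHROCYTE: spec.erythrocyte_fraction * n_nerve,
    }
    total_frac = (
        spec.nervous_fraction
        + spec.adipose_fraction_by_group[record.group]
        + spec.erythrocyte_fraction
    )
    if total_frac > 0.75:
        raise PackingError(
            f"sample {record.sample_id}: requested tissue fractions sum to "
            f"{total_frac:.2f} > 0.75 of the nerve area; cannot pack "
            f"nervous tissue"
        )

    packer = _Packer(rng, nerve_core, (s, s))
    placed_px = {c: 0 for c in budgets}

    def fill(cls, propose, bound, raster, min_area, margin,
             size_lo, size_hi, validate=None, max_attempts=20000):
        """Place components of one class until its pixel budget is met.

        ``propose(remaining, shrink)`` draws a size parameter, ``bound``
        maps it to a bounding radius for EDT candidate-center lookup,
        ``raster(center, size)`` rasterizes one candidate, and ``validate``
        (optional, expensive) vets the accepted shape last.  The size is
        shrunk geometrically whenever no free site can host the current
        bounding radius, down to the class's minimum, at which point the
        fill gives up (the caller checks the achieved-fraction tolerance).
        """
        unorganized = cls == TissueClass.UNORGANIZED_NERVOUS
        blocked = packer.blocked_for_unorg if unorganized else packer.blocked_all
        shrink, attempts, fails = 1.0, 0, 0
        cand, placed_since = None, 0
        while placed_px[cls] < budgets[cls] - min_area / 2 and attempts < max_attempts:
            attempts += 1
            remaining = budgets[cls] - placed_px[cls]
            size = propose(remaining, shrink)
            if cand is None or placed_since >= 12 or fails >= 60:
                # candidate centers: free-space EDT above the largest
                # bounding radius this shrink level can propose; for
                # unorganized, centers too deep inside an existing cluster
                # are dropped so new blobs extend rather than re-cover them
                size_max = max(size_hi * shrink, size_lo)
                cand = packer.candidate_centers(bound(size_max), blocked)
                if unorganized and len(cand):
                    d2u = ndimage.distance_transform_edt(mask != cls)
                    cand = cand[d2u[cand[:, 0], cand[:, 1]] > 0.55 * size_max]
                placed_since, fails = 0, 0
                if len(cand) == 0:
                    if shrink > 0.35:
                        shrink *= 0.8
                        cand = None
                        continue
                    break  # canvas saturated for this class
            center = cand[rng.integers(len(cand))]
            out = raster((float(center[0]), float(center[1])), size)
            if out is None:
                fails += 1
                continue
            rr, cc = out
            if not packer.fits(rr, cc, blocked):
                fails += 1
                continue
            new_px = int((mask[rr, cc] != cls).sum())
            if new_px < min(0.3 * rr.size, remaining):
                fails += 1
                continue
            # tentative placement; validate sees the merged result so the
            # shape guarantee holds per connected component, not per blob
            prev = mask[rr, cc].copy()
            mask[rr, cc] = cls
            if validate is not None and not validate(rr, cc):
                mask[rr, cc] = prev
                fails += 1
                continue
            packer.stamp(rr, cc, margin, unorganized)
            placed_px[cls] += new_px
            placed_since += 1

    # ---- organized fascicles: near-round ellipses, circularity >= 0.7
    r_lo, r_hi = max(6.0, 0.018 * s), 0.065 * s

    def organized_propose(remaining, shrink):
        r_fit = np.sqrt(max(remaining, 1.0) / np.pi)
        return float(np.clip(rng.uniform(0.7, 1.0) * r_hi * shrink, r_lo, max(r_fit, r_lo)))

    def organized_raster(center, r):
        q = rng.uniform(0.78, 1.0)
        return draw.ellipse(
            center[0], center[1], r, r * q,
            shape=(s, s), rotation=rng.uniform(0, np.pi),
        )

    # ---- unorganized tissue: jagged star blobs, circularity <= 0.5
    u_lo, u_hi = max(8.0, 0.025 * s), 0.06 * s

    def unorganized_propose(remaining, shrink):
        # star area is roughly 0.55 * pi * R^2 for the radii used here
        r_fit = np.sqrt(max(remaining, 1.0) / (0.55 * np.pi))
        return float(np.clip(rng.uniform(0.7, 1.0) * u_hi * shrink, u_lo, max(r_fit, u_lo)))

    def unorganized_raster(center, radius):
        pr, pc = _star_polygon(rng, center, radius)
        rr, cc = draw.polygon(pr, pc, shape=(s, s))
        return (rr, cc) if rr.size >= 60 else None

    # ---- adipose vacuoles and erythrocyte specks: plain circles
    def circle_propose(lo, hi):
        return lambda remaining, shrink: float(max(lo, rng.uniform(lo, hi) * shrink))

    def circle_raster(center, r):
        return draw.disk(center, r, shape=(s, s))

    fill(
        TissueClass.ORGANIZED_NERVOUS,
        organized_propose, lambda r: r + 0.5, organized_raster,
        np.pi * r_lo**2, margin=2, size_lo=r_lo, size_hi=r_hi,
        validate=lambda rr, cc: component_roundness(rr, cc) >= 0.7,
    )

    def unorganized_cluster_ok(rr, cc):
        # roundness of the whole merged cluster containing the new blob
        comp = flood(mask == TissueClass.UNORGANIZED_NERVOUS,
                     (int(rr[0]), int(cc[0])), connectivity=2)
        rows, cols = np.nonzero(comp)
        return component_roundness(rows, cols) <= 0.5

    fill(
        TissueClass.UNORGANIZED_NERVOUS,
        unorganized_propose, lambda r: 1.12 * r, unorganized_raster,
        0.55 * np.pi * u_lo**2, margin=2, size_lo=u_lo, size_hi=u_hi,
        validate=unorganized_cluster_ok,
    )
    # vacuoles and specks are not shape-analyzed downstream, so they pack
    # without margins (they may touch each other, never nervous tissue,
    # whose 2-px margin ring is already stamped)
    a_lo, a_hi = max(2.0, 0.008 * s), 0.02 * s
    fill(
        TissueClass.ADIPOSE,
        circle_propose(a_lo, a_hi), lambda r: r, circle_raster,
        np.pi * a_lo**2, margin=0, size_lo=a_lo, size_hi=a_hi,
    )
    fill(
        TissueClass.ERYTHROCYTE,
        circle_propose(1.5, 3.0), lambda r: r, circle_raster,
        8, margin=0, size_lo=1.5, size_hi=3.0,
    )

    org = placed_px[TissueClass.ORGANIZED_NERVOUS]
    unorg = placed_px[TissueClass.UNORGANIZED_NERVOUS]
    if org + unorg == 0:
        achieved = f_org  # no nervous budget requested at all
    else:
        achieved = org / (org + unorg)
    if abs(achieved - f_org) > 0.1:
        failing = (
            "organized_nervous" if achieved < f_org else "unorganized_nervous"
        )
        raise PackingError(
            f"sample {record.sample_id}: achieved organized fraction "
            f"{achieved:.3f} deviates > 0.1 from target {f_org:.3f}; "
            f"could not pack enough {failing} tissue"
        )

    image = _colorize(rng, mask, spec.noise_sigma)
    fractions = rendered_fractions(mask)
    return GroundTruthSample(
        image=image, truth_mask=mask, record=record, rendered_fractions=fractions
    )


def _colorize(rng: np.random.Generator, mask: np.ndarray, noise_sigma: float) -> np.ndarray:
    """Turn a truth mask into a noisy EvG-like RGB rendering."""
    s = mask.shape[0]
    img = np.empty(mask.shape + (3,), dtype=np.float64)
    for code, rgb in PALETTE.items():
        jitter = rng.normal(0.0, 3.0, size=3)
        img[mask == code] = np.asarray(rgb, dtype=float) + jitter
    # low-frequency illumination gradient (multiplicative, +-4 %)
    gy, gx = rng.uniform(-1, 1, 2)
    r_ax = (np.arange(s) / s - 0.5)
    gradient = 1.0 + 0.04 * (gy * r_ax[:, None] + gx * r_ax[None, :])
    img *= gradient[..., None]
    # mild smooth texture shared across channels
    texture = gaussian_filter(rng.standard_normal(mask.shape), 2.0) * 5.0
    img += texture[..., None]
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def rendered_fractions(mask: np.ndarray) -> dict[str, float]:
    """Per-class fraction of non-background pixels in a truth mask."""
    tissue = mask != TissueClass.BACKGROUND
    total = int(tissue.sum())
    out = {}
    for cls in TissueClass:
        if cls == TissueClass.BACKGROUND:
            continue
        out[cls.name.lower()] = (
            int((mask == cls).sum()) / total if total else 0.0
        )
    return out


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _sample_seeds(spec: CohortSpec) -> list[int]:
    state = np.random.SeedSequence([spec.seed, 0x5A]).generate_state(spec.n_total)
    return [int(x) % (2**31) for x in state]


def iter_samples(spec: CohortSpec):
    """Yield every :class:`GroundTruthSample` of the cohort, in record order."""
    records = build_records(spec)
    for record, seed in zip(records, _sample_seeds(spec)):
        yield render_sample(spec, record, seed)


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> dict:
    """Render the whole cohort to disk and return the JSON manifest.

    Writes, per sample, ``<id>_image.png`` and ``<id>_mask.png``, plus
    ``cohort.csv`` (metadata) and ``manifest.json`` (spec echo, per-sample
    seeds, palette, rendered fractions, file checksums).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = build_records(spec)
    seeds = _sample_seeds(spec)
    samples_meta = []
    for record, seed in zip(records, seeds):
        sample = render_sample(spec, record, seed)
        img_path = out_dir / f"{record.sample_id}_image.png"
        mask_path = out_dir / f"{record.sample_id}_mask.png"
        write_image(sample.image, img_path)
        write_mask(sample.truth_mask, mask_path)
        samples_meta.append(
            dict(
                sample_id=record.sample_id,
                seed=seed,
                image=img_path.name,
                mask=mask_path.name,
                image_sha256=_sha256(img_path),
                mask_sha256=_sha256(mask_path),
                rendered_fractions=sample.rendered_fractions,
                organized_target=spec.organized_target(record),
            )
        )
    csv_path = out_dir / "cohort.csv"
    write_cohort_table(records, csv_path)
    manifest = dict(
        spec=_spec_to_dict(spec),
        palette={str(k): list(v) for k, v in PALETTE.items()},
        samples=samples_meta,
        cohort_csv=csv_path.name,
    )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _spec_to_dict(spec: CohortSpec) -> dict:
    d = {}
    for k, v in vars(spec).items():
        if isinstance(v, tuple):
            v = list(v)
        d[k] = v
    return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
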