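"""Synthetic multimodal hemorrhage cases: brain phantoms, subtype-specific
lesions, temporal progression sequences, templated clinical notes, labels
and dataset manifests.

The phantom is a deliberately simple axial-slice stand-in: an elliptical
brain with a bright skull ring, darker ventricles and Gaussian tissue
noise.  Each hemorrhage subtype gets the geometry radiologists use to
recognize it — a parenchymal blob for ICH, a crescent hugging the inner
skull for SDH, a biconvex lens at the skull for EDH, blood confined to the
ventricles for IVH, and a thin rim along the brain boundary for SAH.
Progression follows an expand-then-resorb trajectory: the lesion grows up
to a peak frame, then shrinks while its intensity offset decays toward the
hypodense chronic phase.

Every random draw flows from named substreams of a single run seed, so any
case or note can be regenerated in isolation.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PhantomSpec",
    "LesionSpec",
    "ProgressionParams",
    "CaseRecord",
    "DatasetManifest",
    "SUBTYPES",
    "SUBTYPE_NAMES",
    "RISK_LEVELS",
    "TABLE2_COUNTS",
    "NOTE_KINDS",
    "generate_phantom",
    "phantom_masks",
    "lesion_mask",
    "render_lesion",
    "simulate_progression",
    "progression_masks",
    "sequence_mse",
    "select_model_by_mse",
    "generate_clinical_note",
    "assign_labels",
    "make_case",
    "build_manifest",
    "benchmark_counts",
    "template_words",
]

logger = logging.getLogger(__name__)

SUBTYPES = ("ICH", "SDH", "EDH", "IVH", "SAH")

SUBTYPE_NAMES = {
    "ICH": "intracerebral hemorrhage",
    "SDH": "subdural hemorrhage",
    "EDH": "extradural hemorrhage",
    "IVH": "intraventricular hemorrhage",
    "SAH": "subarachnoid hemorrhage",
    "MIXED": "mixed hemorrhage",
}

#: Dementia-risk level by hemorrhage subtype.  SAH (Moderate) and MIXED
#: (Moderate to High) extend the four canonical entries.
RISK_LEVELS = {
    "ICH": "High",
    "SDH": "Moderate",
    "EDH": "Low",
    "IVH": "Moderate to High",
    "SAH": "Moderate",
    "MIXED": "Moderate to High",
}

#: Per-split, per-subtype case counts of the reference dataset blueprint
#: (10 images per case): 378/73/75 cases, 3,780/730/750 images.
TABLE2_COUNTS = {
    "train": {"ICH": 142, "SDH": 91, "EDH": 58, "IVH": 49, "MIXED": 38},
    "validation": {"ICH": 26, "SDH": 17, "EDH": 11, "IVH": 9, "MIXED": 10},
    "test": {"ICH": 28, "SDH": 18, "EDH": 12, "IVH": 10, "MIXED": 7},
}

NOTE_KINDS = ("consultation", "progression", "procedural", "radiology")

SENTIMENTS = ("positive", "negative", "neutral", "uncertain")


def _substream(seed: int, *tags) -> np.random.Generator:
    """Named, order-independent substream of a run seed."""
    ints = [int(seed) & 0x7FFFFFFF]
    for tag in tags:
        ints.append(zlib.crc32(str(tag).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(ints)


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and texture of one synthetic axial brain slice."""

    image_height_px: int = 64
    image_width_px: int = 64
    brain_ellipse: tuple[float, float, float, float] = (32.0, 32.0, 26.0, 22.0)
    skull_thickness_px: int = 2
    ventricle_ellipses: tuple[tuple[float, float, float, float], ...] = (
        (30.0, 25.0, 6.0, 3.0),
        (30.0, 39.0, 6.0, 3.0),
    )
    tissue_mean_intensity: float = 120.0
    noise_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0 <= self.noise_sigma < 64:
            raise ValueError("noise_sigma must lie in [0, 64)")
        if not 0 <= self.tissue_mean_intensity <= 255:
            raise ValueError("tissue_mean_intensity must lie in [0, 255]")
        brain, vents = _ellipse_masks(self)
        for vmask in vents:
            if not np.all(brain[vmask]):
                raise ValueError("ventricle ellipse lies outside the brain ellipse")


def _ellipse(shape: tuple[int, int], params: tuple[float, float, float, float]) -> np.ndarray:
    cr, cc, ar, ac = params
    rr, cc_ = np.ogrid[: shape[0], : shape[1]]
    return ((rr - cr) / ar) ** 2 + ((cc_ - cc) / ac) ** 2 <= 1.0


@lru_cache(maxsize=256)
def _ellipse_masks(spec: PhantomSpec) -> tuple[np.ndarray, tuple[np.ndarray, ...]]:
    shape = (spec.image_height_px, spec.image_width_px)
    brain = _ellipse(shape, spec.brain_ellipse)
    vents = tuple(_ellipse(shape, v) for v in spec.ventricle_ellipses)
    return brain, vents


def phantom_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """(brain_mask, ventricle_mask) for a phantom spec."""
    brain, vents = _ellipse_masks(spec)
    vent = np.zeros_like(brain)
    for v in vents:
        vent |= v
    return brain.copy(), vent


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render the phantom: dim background, bright skull ring, tissue at
    tissue_mean_intensity +/- noise, darker ventricles.  Deterministic for a
    fixed seed."""
    shape = (spec.image_height_px, spec.image_width_px)
    brain, vent = phantom_masks(spec)
    cr, cc, ar, ac = spec.brain_ellipse
    skull_outer = _ellipse(
        shape, (cr, cc, ar + spec.skull_thickness_px, ac + spec.skull_thickness_px)
    )
    img = np.full(shape, 15.0)
    img[skull_outer & ~brain] = 230.0
    img[brain] = spec.tissue_mean_intensity
    img[vent] = max(spec.tissue_mean_intensity - 60.0, 5.0)
    if spec.noise_sigma > 0:
        rng = _substream(spec.seed, "phantom-noise")
        noise = rng.normal(0.0, spec.noise_sigma, shape)
        img[brain] += noise[brain]
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Lesions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LesionSpec:
    """One hemorrhagic lesion; geometry is determined by the subtype.

    SDH and SAH share a boundary-band geometry family parameterized by the
    band width and angular extent; their defaults (SDH: wide 120-degree
    crescent, SAH: thin full-circumference rim) can be overridden to render
    intermediate, radiologically ambiguous collections.
    """

    subtype: str
    center: tuple[float, float]
    base_radius_px: float
    intensity_offset: float = 70.0
    band_width_px: float | None = None
    band_extent_deg: float | None = None

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPE_NAMES:
            raise ValueError(f"unknown subtype {self.subtype!r}; expected one of {sorted(SUBTYPE_NAMES)}")
        if self.base_radius_px <= 0:
            raise ValueError("base_radius_px must be positive")


def _disc(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _normalized_radius(shape: tuple[int, int], brain: tuple[float, float, float, float]) -> np.ndarray:
    cr, cc, ar, ac = brain
    rr, cc_ = np.ogrid[: shape[0], : shape[1]]
    return np.sqrt(((rr - cr) / ar) ** 2 + ((cc_ - cc) / ac) ** 2) + np.zeros(shape)


def lesion_mask(lesion: LesionSpec, phantom: PhantomSpec) -> np.ndarray:
    """Boolean lesion mask for a subtype geometry, clipped to the brain.

    ICH: parenchymal disc.  SDH: crescent along the inner skull (an angular
    sector of a boundary band).  EDH: biconvex lens straddling the inner
    skull.  IVH: disc clipped to the ventricles.  SAH: thin rim along the
    whole brain boundary.
    """
    shape = (phantom.image_height_px, phantom.image_width_px)
    brain, vent = phantom_masks(phantom)
    cr, cc, ar, ac = phantom.brain_ellipse
    sub = lesion.subtype
    r = lesion.base_radius_px

    if sub == "ICH":
        return _disc(shape, lesion.center, r) & brain
    if sub == "IVH":
        return _disc(shape, lesion.center, r) & vent

    e = _normalized_radius(shape, phantom.brain_ellipse)
    # direction from the brain center to the lesion site
    dr, dc = lesion.center[0] - cr, lesion.center[1] - cc
    norm = float(np.hypot(dr, dc))
    u = (dr / norm, dc / norm) if norm > 0 else (0.0, 1.0)

    if sub in ("SDH", "SAH"):
        if sub == "SDH":
            width_px = lesion.band_width_px if lesion.band_width_px is not None else r
            extent = lesion.band_extent_deg if lesion.band_extent_deg is not None else 120.0
        else:
            width_px = (
                lesion.band_width_px
                if lesion.band_width_px is not None
                else max(1.5, r / 3.0)
            )
            extent = lesion.band_extent_deg if lesion.band_extent_deg is not None else 360.0
        band = brain & (e >= 1.0 - width_px / min(ar, ac))
        if extent >= 360.0:
            return band
        rr, cc_ = np.ogrid[: shape[0], : shape[1]]
        cosang = ((rr - cr) * u[0] + (cc_ - cc) * u[1]) / np.maximum(
            np.hypot(rr - cr, cc_ - cc), 1e-9
        )
        return band & (cosang >= np.cos(np.deg2rad(extent / 2.0)))

    if sub == "EDH":
        # boundary point along u, two overlapping discs across the boundary
        t = 1.0 / np.sqrt((u[0] / ar) ** 2 + (u[1] / ac) ** 2)
        pb = (cr + u[0] * t, cc + u[1] * t)
        inner = (pb[0] - u[0] * r * 0.5, pb[1] - u[1] * r * 0.5)
        outer = (pb[0] + u[0] * r * 0.5, pb[1] + u[1] * r * 0.5)
        return _disc(shape, inner, r) & _disc(shape, outer, r) & brain

    raise ValueError(f"no geometry for subtype {sub!r}")


def _edema_halo(lesion: LesionSpec, phantom: PhantomSpec, mask: np.ndarray) -> np.ndarray:
    shape = (phantom.image_height_px, phantom.image_width_px)
    brain, _ = phantom_masks(phantom)
    halo = _disc(shape, lesion.center, lesion.base_radius_px * 1.6) & brain & ~mask
    return halo


def render_lesion(base: np.ndarray, lesion: LesionSpec, phantom: PhantomSpec) -> np.ndarray:
    """Shift pixels inside the lesion mask by the intensity offset (clamped
    to 8-bit); ICH lesions get a softer edema halo at 40% of the offset."""
    mask = lesion_mask(lesion, phantom)
    if not mask.any():
        raise ValueError(
            f"{lesion.subtype} lesion mask is empty after clipping: the lesion "
            f"geometry at {lesion.center} does not intersect its required region "
            f"({'ventricle mask' if lesion.subtype == 'IVH' else 'brain mask'})"
        )
    out = np.asarray(base, dtype=float).copy()
    out[mask] += lesion.intensity_offset
    if lesion.subtype == "ICH" and lesion.intensity_offset != 0:
        out[_edema_halo(lesion, phantom, mask)] += 0.4 * lesion.intensity_offset
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Temporal progression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProgressionParams:
    """Expand-then-resorb trajectory over n_frames time points.

    The lesion radius is multiplied by growth_factor_per_frame up to the
    peak frame (index (n_frames-1)//2) and by shrink_factor_per_frame after
    it; the intensity offset decays by intensity_decay_per_frame per frame
    past the peak (hyperdense -> hypodense trend).  shrink > 1 models a
    worsening course; shrink == 1 with zero decay is the indeterminate
    (uncertain) course.
    """

    n_frames: int = 5
    growth_factor_per_frame: float = 1.3
    shrink_factor_per_frame: float = 0.7
    intensity_decay_per_frame: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.growth_factor_per_frame < 1:
            raise ValueError("growth_factor_per_frame must be >= 1")
        if self.shrink_factor_per_frame <= 0:
            raise ValueError("shrink_factor_per_frame must be positive")
        if not 0 <= self.intensity_decay_per_frame < 1:
            raise ValueError("intensity_decay_per_frame must lie in [0, 1)")

    @property
    def peak_frame(self) -> int:
        return (self.n_frames - 1) // 2


def _lesion_at_frame(lesion: LesionSpec, params: ProgressionParams, t: int) -> LesionSpec:
    peak = params.peak_frame
    factor = params.growth_factor_per_frame ** min(t, peak)
    factor *= params.shrink_factor_per_frame ** max(0, t - peak)
    offset = lesion.intensity_offset * (1 - params.intensity_decay_per_frame) ** max(
        0, t - peak
    )
    width = (
        lesion.band_width_px * factor if lesion.band_width_px is not None else None
    )
    return replace(lesion, base_radius_px=lesion.base_radius_px * factor,
                   intensity_offset=offset, band_width_px=width)


def progression_masks(
    lesion: LesionSpec, params: ProgressionParams, phantom: PhantomSpec
) -> list[np.ndarray]:
    """Per-frame lesion masks (already clipped to the brain/ventricles)."""
    return [
        lesion_mask(_lesion_at_frame(lesion, params, t), phantom)
        for t in range(params.n_frames)
    ]


def simulate_progression(
    base: np.ndarray,
    lesion: LesionSpec,
    params: ProgressionParams,
    phantom: PhantomSpec,
) -> list[np.ndarray]:
    """Render the lesion trajectory onto a fixed base slice.

    Frame 0 is base+lesion; the lesion grows to the peak frame, then
    shrinks and fades.  A lesion growing beyond the brain is clipped to the
    brain mask with a logged warning.  Returns exactly n_frames images.
    """
    brain, _ = phantom_masks(phantom)
    shape = (phantom.image_height_px, phantom.image_width_px)
    frames = []
    for t in range(params.n_frames):
        frame_lesion = _lesion_at_frame(lesion, params, t)
        if frame_lesion.subtype == "ICH":
            unclipped = _disc(shape, frame_lesion.center, frame_lesion.base_radius_px)
            if (unclipped & ~brain).any():
                logger.warning(
                    "frame %d lesion exceeds the brain mask; clipping", t
                )
        frames.append(render_lesion(base, frame_lesion, phantom))
    return frames


def sequence_mse(generated: list[np.ndarray], reference: list[np.ndarray]) -> float:
    """Mean squared error averaged over time stamps and pixels:
    sum_t sum_xy (gen - ref)^2 / (T * N)."""
    if len(generated) != len(reference):
        raise ValueError("sequence lengths differ")
    if not generated:
        raise ValueError("empty sequences")
    total = 0.0
    n_pix = None
    for g, r in zip(generated, reference):
        g = np.asarray(g, dtype=float)
        r = np.asarray(r, dtype=float)
        if g.shape != r.shape:
            raise ValueError("frame shapes differ")
        if n_pix is None:
            n_pix = g.size
        total += float(np.sum((g - r) ** 2))
    return total / (len(generated) * n_pix)


def select_model_by_mse(
    candidates: list[ProgressionParams],
    reference: list[np.ndarray],
    base: np.ndarray,
    lesion: LesionSpec,
    phantom: PhantomSpec,
) -> tuple[ProgressionParams, pd.DataFrame]:
    """Generate a sequence per candidate configuration and pick the one
    with minimum sequence MSE against the reference (ties broken by list
    order).  Also returns the full per-candidate table with MSE, mean SSIM
    and PSNR."""
    from .metrics import psnr, ssim

    if not candidates:
        raise ValueError("candidate list is empty")
    rows = []
    mses = []
    for idx, cand in enumerate(candidates):
        if cand.n_frames != len(reference):
            raise ValueError(
                f"candidate {idx} has n_frames={cand.n_frames}, reference has {len(reference)}"
            )
        frames = simulate_progression(base, lesion, cand, phantom)
        mse = sequence_mse(frames, reference)
        mses.append(mse)
        rows.append(
            {
                "config": (
                    f"growth={cand.growth_factor_per_frame}, "
                    f"shrink={cand.shrink_factor_per_frame}, "
                    f"decay={cand.intensity_decay_per_frame}"
                ),
                "mse": mse,
                "ssim": float(np.mean([ssim(r, g) for r, g in zip(reference, frames)])),
                "psnr_db": float(np.mean([psnr(r, g) for r, g in zip(reference, frames)])),
            }
        )
    best = int(np.argmin(mses))  # argmin keeps the first index on ties
    return candidates[best], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------


def assign_labels(
    lesion: LesionSpec, params: ProgressionParams, phantom: PhantomSpec
) -> tuple[str, str, str]:
    """(prognosis_sentiment, therapeutic_sentiment, risk_level).

    Prognosis follows the lesion-area trajectory: uncertain when the course
    is indeterminate (shrink == 1 and no intensity decay), positive when the
    final area is below the initial area, negative when it exceeds the peak
    area, neutral otherwise.  Therapeutic sentiment tracks the resorption
    factor: positive when shrink < 1, negative when shrink > 1, otherwise
    neutral (or uncertain with no decay).  Risk comes from the fixed
    subtype map.  Pure and deterministic.
    """
    areas = [int(m.sum()) for m in progression_masks(lesion, params, phantom)]
    peak = params.peak_frame
    s = params.shrink_factor_per_frame
    d = params.intensity_decay_per_frame
    if s == 1.0 and d == 0.0:
        prognosis = "uncertain"
    elif areas[-1] < areas[0]:
        prognosis = "positive"
    elif areas[-1] > areas[peak]:
        prognosis = "negative"
    else:
        prognosis = "neutral"
    if s < 1.0:
        therapeutic = "positive"
    elif s > 1.0:
        therapeutic = "negative"
    else:
        therapeutic = "uncertain" if d == 0.0 else "neutral"
    return prognosis, therapeutic, RISK_LEVELS[lesion.subtype]


# ---------------------------------------------------------------------------
# Clinical notes
# ---------------------------------------------------------------------------

_INTRO = {
    "consultation": (
        "Consultation note for patient {pid} referred to the neurosurgical service "
        "for evaluation of {name} identified on axial brain imaging ."
    ),
    "progression": (
        "Progression note for patient {pid} documenting serial imaging findings "
        "and clinical course of the known {name} across the observation interval ."
    ),
    "procedural": (
        "Procedural note for patient {pid} describing the operative approach , "
        "intraoperative findings and postoperative plan for the {name} ."
    ),
    "radiology": (
        "Radiology report for patient {pid} . Serial axial images demonstrate a "
        "{name} with evolving density and volume across five time points ."
    ),
}

_FRAME_SENTENCE = (
    "At time {t} the lesion measures approximately {area} square millimeters with an "
    "estimated diameter of {diam} millimeters and {dens} density relative to adjacent tissue ."
)

_SENTIMENT_SENTENCES = {
    "positive": [
        "Interval imaging suggests a favorable outcome with progressive resorption of the collection .",
        "The clinical course is consistent with recovery and improved survival is anticipated .",
        "The patient remains stable and a good outcome is expected with continued monitoring .",
    ],
    "negative": [
        "The enlarging collection now constitutes a large hematoma with worsening regional pressure .",
        "Depressed consciousness approaching coma has been documented on serial examinations .",
        "Advanced old age and lesion expansion raise concern for a poor neurological course .",
    ],
    "neutral": [
        "The glasgow coma scale score and hematoma volume were recorded at each assessment .",
        "There is measurable midline shift with associated mass effect on the adjacent ventricle .",
        "Perihematomal edema is noted in the supratentorial compartment without new findings .",
    ],
    "uncertain": [
        "The trajectory remains indeterminate and serial hematoma volume measurements are advised .",
        "Findings are equivocal ; the gcs has fluctuated and no definite trend is established .",
        "It is unclear whether the collection will expand or resorb over the coming interval .",
    ],
}

_THERAPEUTIC_SENTENCES = {
    "positive": [
        "Response to therapy has been encouraging with measurable reduction in lesion size .",
        "Surgical management achieved satisfactory decompression and the course suggests recovery .",
    ],
    "negative": [
        "Despite intervention the large hematoma persists and therapeutic options are limited .",
        "Treatment response has been poor with continued expansion of the collection .",
    ],
    "neutral": [
        "Management continues per protocol with scheduled reassessment of hematoma volume .",
        "Supportive care is maintained while monitoring the mass effect on follow up imaging .",
    ],
    "uncertain": [
        "The benefit of further intervention is uncertain pending repeat imaging .",
        "Therapeutic yield cannot yet be judged ; the gcs trend will guide escalation .",
    ],
}

_FILLER = [
    "Vital signs remain within acceptable limits and laboratory values are unremarkable .",
    "The patient tolerated the imaging examination without complication or sedation .",
    "Neurological examination documented symmetric motor responses in all extremities .",
    "Blood pressure control continues with the established antihypertensive regimen .",
    "No new focal deficit was elicited on the most recent bedside assessment .",
    "The family was counselled regarding the findings and the monitoring plan .",
    "Repeat imaging is scheduled to document the interval change in the collection .",
    "Hydration and electrolyte balance are maintained with routine supportive measures .",
    "Nursing staff will continue hourly neurological observations overnight .",
    "The anticoagulation history was reviewed and no contraindication was identified .",
    "Seizure prophylaxis was discussed and deferred in the absence of cortical irritation .",
    "Mobilization will proceed as tolerated under physiotherapy supervision .",
]

_PLAN = (
    "Plan : continue close observation , repeat axial imaging at the next interval , "
    "and reassess the prognosis after the follow up study . The differential review "
    "considered {d1} and {d2} before the working impression was retained ."
)

_TOKEN_TARGET = 520
_TOKEN_MIN, _TOKEN_MAX = 400, 900


def template_words() -> set[str]:
    """All lowercase words appearing in the packaged note templates (used to
    seed the default WordPiece vocabulary)."""
    import string as _string

    chunks = list(_INTRO.values()) + [_FRAME_SENTENCE, _PLAN] + _FILLER
    for group in (_SENTIMENT_SENTENCES, _THERAPEUTIC_SENTENCES):
        for sents in group.values():
            chunks.extend(sents)
    chunks.extend(SUBTYPE_NAMES.values())
    words = set()
    for chunk in chunks:
        for raw in chunk.lower().split():
            w = raw.strip(_string.punctuation)
            if w and "{" not in w:
                words.add(w)
    return words


def generate_clinical_note(case: "CaseRecord", kind: str, seed: int) -> str:
    """Template-expanded clinical note for one case.

    Deterministic for a fixed (case, kind, seed).  The note embeds the
    subtype name, the per-frame size trajectory, sentiment-consistent
    lexicon terms, a two-item differential of other subtypes, and generic
    filler sentences until the whitespace token count lands in [400, 900].
    """
    if kind not in NOTE_KINDS:
        raise ValueError(f"unknown note kind {kind!r}; valid kinds: {NOTE_KINDS}")
    rng = _substream(seed, "note", kind, case.case_id)
    name = SUBTYPE_NAMES[case.subtype]
    parts = [_INTRO[kind].format(pid=case.case_id, name=name)]

    areas = case.frame_areas or [0] * 5
    peak = (len(areas) - 1) // 2
    for t, area in enumerate(areas):
        dens = "hyperdense" if t <= peak else "decreasing"
        diam = max(1, int(round(2.0 * np.sqrt(max(area, 1) / np.pi))))
        parts.append(_FRAME_SENTENCE.format(t=t, area=int(area), diam=diam, dens=dens))

    prog_pool = _SENTIMENT_SENTENCES[case.prognosis_sentiment]
    ther_pool = _THERAPEUTIC_SENTENCES[case.therapeutic_sentiment]
    parts.extend(rng.choice(prog_pool, size=2, replace=False))
    parts.append(str(rng.choice(ther_pool)))

    others = [s for s in SUBTYPE_NAMES if s not in (case.subtype, "MIXED")]
    d1, d2 = rng.choice(others, size=2, replace=False)
    parts.append(_PLAN.format(d1=SUBTYPE_NAMES[d1], d2=SUBTYPE_NAMES[d2]))

    text = " ".join(parts)
    filler = list(_FILLER)
    rng.shuffle(filler)
    i = 0
    while len(text.split()) < _TOKEN_TARGET:
        text += " " + filler[i % len(filler)]
        i += 1
    n_tokens = len(text.split())
    assert _TOKEN_MIN <= n_tokens <= _TOKEN_MAX, n_tokens
    return text


# ---------------------------------------------------------------------------
# Cases and manifest
# ---------------------------------------------------------------------------


@dataclass
class CaseRecord:
    """One synthetic patient: subtype, temporal frames, notes and labels."""

    case_id: str
    subtype: str
    split: str
    frames: list[np.ndarray] = field(default_factory=list, repr=False)
    notes: dict[str, str] = field(default_factory=dict, repr=False)
    prognosis_sentiment: str = "uncertain"
    therapeutic_sentiment: str = "uncertain"
    risk_level: str = ""
    frame_areas: list[int] = field(default_factory=list)
    lesion: LesionSpec | None = None
    progression: ProgressionParams | None = None
    phantom: PhantomSpec | None = None


#: Fraction of SDH/SAH cases rendered with an intermediate boundary-band
#: appearance that image geometry alone cannot attribute to a compartment;
#: the clinical note still names the true subtype, so the modalities carry
#: complementary information.
AMBIGUOUS_BAND_FRACTION = 0.2

#: The four packaged progression regimes; cycled across the cases of each
#: subtype so all sentiment classes appear in every split.
SENTIMENT_REGIMES = (
    ("improving", dict(growth_factor_per_frame=1.3, shrink_factor_per_frame=0.65,
                       intensity_decay_per_frame=0.3)),
    ("worsening", dict(growth_factor_per_frame=1.25, shrink_factor_per_frame=1.25,
                       intensity_decay_per_frame=0.0)),
    ("stable", dict(growth_factor_per_frame=1.15, shrink_factor_per_frame=0.95,
                    intensity_decay_per_frame=0.1)),
    ("uncertain", dict(growth_factor_per_frame=1.2, shrink_factor_per_frame=1.0,
                       intensity_decay_per_frame=0.0)),
)


def _sample_lesion(subtype: str, phantom: PhantomSpec, rng: np.random.Generator) -> LesionSpec:
    cr, cc, ar, ac = phantom.brain_ellipse
    if subtype == "ICH":
        center = (cr + rng.uniform(-6, 6), cc + rng.uniform(-6, 6))
        return LesionSpec("ICH", center, rng.uniform(4.5, 7.0))
    if subtype == "IVH":
        v = phantom.ventricle_ellipses[rng.integers(len(phantom.ventricle_ellipses))]
        center = (v[0] + rng.uniform(-2, 2), v[1] + rng.uniform(-1, 1))
        return LesionSpec("IVH", center, rng.uniform(3.5, 5.5))
    angle = rng.uniform(0, 2 * np.pi)
    direction = (np.sin(angle), np.cos(angle))
    center = (cr + direction[0] * ar * 0.8, cc + direction[1] * ac * 0.8)
    if subtype == "EDH":
        return LesionSpec("EDH", center, rng.uniform(5.0, 7.5))
    if subtype in ("SDH", "SAH"):
        r = rng.uniform(2.5, 4.0) if subtype == "SDH" else rng.uniform(4.0, 6.0)
        # a fraction of boundary collections render with an intermediate,
        # radiologically ambiguous width/extent that geometry alone cannot
        # attribute to the subdural vs subarachnoid compartment
        if rng.uniform() < AMBIGUOUS_BAND_FRACTION:
            return LesionSpec(
                subtype, center, r,
                band_width_px=float(rng.uniform(1.8, 2.6)),
                band_extent_deg=float(rng.uniform(200.0, 260.0)),
            )
        return LesionSpec(subtype, center, r)
    raise ValueError(f"cannot sample lesion for {subtype!r}")


def make_case(
    case_id: str,
    subtype: str,
    split: str,
    regime_idx: int,
    seed: int,
    n_frames: int = 5,
    image_size: int = 64,
    noise_sigma: float = 8.0,
) -> CaseRecord:
    """Build one fully-populated case (phantom, frames, labels, notes)."""
    rng = _substream(seed, "case", case_id)
    phantom = PhantomSpec(
        image_height_px=image_size,
        image_width_px=image_size,
        noise_sigma=noise_sigma,
        seed=int(rng.integers(2**31 - 1)),
    )
    _, regime = SENTIMENT_REGIMES[regime_idx % len(SENTIMENT_REGIMES)]
    params = ProgressionParams(n_frames=n_frames, seed=int(rng.integers(2**31 - 1)), **regime)

    base = generate_phantom(phantom)
    if subtype == "MIXED":
        s1, s2 = rng.choice(SUBTYPES, size=2, replace=False)
        lesion = _sample_lesion(str(s1), phantom, rng)
        second = _sample_lesion(str(s2), phantom, rng)
        base = render_lesion(base, second, phantom)
    else:
        lesion = _sample_lesion(subtype, phantom, rng)
    frames = simulate_progression(base, lesion, params, phantom)
    areas = [int(m.sum()) for m in progression_masks(lesion, params, phantom)]
    prognosis, therapeutic, _ = assign_labels(lesion, params, phantom)
    risk = RISK_LEVELS[subtype]

    case = CaseRecord(
        case_id=case_id,
        subtype=subtype,
        split=split,
        frames=frames,
        prognosis_sentiment=prognosis,
        therapeutic_sentiment=therapeutic,
        risk_level=risk,
        frame_areas=areas,
        lesion=lesion,
        progression=params,
        phantom=phantom,
    )
    note_seed = int(rng.integers(2**31 - 1))
    case.notes = {kind: generate_clinical_note(case, kind, note_seed) for kind in NOTE_KINDS}
    return case


@dataclass
class DatasetManifest:
    """Case bookkeeping: per-split/per-subtype counts plus the case records."""

    cases: list[CaseRecord]
    frames_per_case: int
    counts: dict[str, dict[str, int]]

    def cases_total(self, split: str | None = None) -> int:
        if split is None:
            return len(self.cases)
        return sum(1 for c in self.cases if c.split == split)

    def images_total(self, split: str | None = None) -> int:
        return self.cases_total(split) * self.frames_per_case

    @property
    def splits(self) -> list[str]:
        return sorted({c.split for c in self.cases})

    def split_cases(self, split: str) -> list[CaseRecord]:
        return [c for c in self.cases if c.split == split]

    def to_json(self, path: str | Path | None = None) -> dict:
        schema = {
            "frames_per_case": self.frames_per_case,
            "splits": {
                split: {
                    subtype: [c.case_id for c in self.cases
                              if c.split == split and c.subtype == subtype]
                    for subtype in sorted({c.subtype for c in self.split_cases(split)})
                }
                for split in self.splits
            },
            "totals": {
                "cases": self.cases_total(),
                "images": self.images_total(),
                **{
                    split: {"cases": self.cases_total(split), "images": self.images_total(split)}
                    for split in self.splits
                },
            },
        }
        if path is not None:
            Path(path).write_text(json.dumps(schema, indent=2), encoding="utf-8")
        return schema

    def frame_index(self) -> pd.DataFrame:
        """Flat image index: one row per (case, frame slot).  When
        frames_per_case exceeds the stored frame count, stored frames are
        cycled across the slots."""
        rows = []
        for c in self.cases:
            n_stored = len(c.frames)
            for k in range(self.frames_per_case):
                rows.append(
                    {
                        "case_id": c.case_id,
                        "split": c.split,
                        "subtype": c.subtype,
                        "frame_idx": k,
                        "stored_frame": k % max(n_stored, 1),
                        "path": f"{c.split}/{c.case_id}/frame_{k:02d}.png",
                        "prognosis_sentiment": c.prognosis_sentiment,
                        "therapeutic_sentiment": c.therapeutic_sentiment,
                        "risk_level": c.risk_level,
                    }
                )
        return pd.DataFrame(rows)


def build_manifest(
    counts: dict[str, dict[str, int]],
    frames_per_case: int = 10,
    seed: int = 0,
    n_frames: int = 5,
    image_size: int = 64,
    noise_sigma: float = 8.0,
) -> DatasetManifest:
    """Generate counts[split][subtype] cases per cell and assemble the
    manifest; images_total == cases_total * frames_per_case by construction."""
    if frames_per_case < 1:
        raise ValueError("frames_per_case must be >= 1")
    cases: list[CaseRecord] = []
    for split in counts:
        for subtype, n in counts[split].items():
            if n < 0:
                raise ValueError(f"negative case count for {split}/{subtype}")
            for i in range(n):
                case_id = f"{split}-{subtype}-{i:03d}"
                cases.append(
                    make_case(
                        case_id, subtype, split, regime_idx=i, seed=seed,
                        n_frames=n_frames, image_size=image_size,
                        noise_sigma=noise_sigma,
                    )
                )
    return DatasetManifest(cases=cases, frames_per_case=frames_per_case,
                           counts={s: dict(v) for s, v in counts.items()})


def benchmark_counts(n_train: int = 70, n_val: int = 15, n_test: int = 15) -> dict:
    """Balanced five-subtype counts for the packaged classification
    benchmark (default 100 cases per subtype, 500 total)."""
    return {
        "train": {s: n_train for s in SUBTYPES},
        "validation": {s: n_val for s in SUBTYPES},
        "test": {s: n_test for s in SUBTYPES},
    }
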