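"""Synthetic two-group landmark cohorts with regional genotype effects.

The generator emulates the design of a mouse craniofacial phenotyping
cohort: a fixed template anatomy (landmarks on a stylized half-ellipsoid
"skull" surface, grouped into contiguous anatomical regions), a wild-type
group sampled as template + isotropic Gaussian landmark noise, and an
affected group whose template is first deformed by a regional displacement
field — e.g. midface contraction, lateral (mediolateral) expansion of the
neurocranium, or occipital shortening — before the same noise is added.
Optional nuisance rigid motions (rotation, translation, uniform scale
jitter) emulate arbitrary specimen pose in the scanner.

Randomness is counter-based: every specimen draws from its own
``numpy.random.SeedSequence`` child keyed by (group, index), so enlarging a
cohort never perturbs previously generated specimens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .io import LandmarkConfiguration, SpecimenSet

#: semi-axes (anteroposterior, mediolateral, dorsoventral) of the template
#: surface, in mm; sized like an adult mouse cranium (~22 mm long).
DEFAULT_SEMI_AXES = (11.0, 6.5, 5.0)

#: desk-scale default regions for simulation studies, as front-to-back
#: sectors in anatomical order: the frontal region separates the midface
#: from the (parietal/interparietal) neurocranium, as it does in the skull.
DESK_REGIONS = (("midface", 4), ("frontal", 4), ("neurocranium", 4))


@dataclass(frozen=True)
class Template:
    """A fixed landmark anatomy: names, region tags, and 3D coordinates."""

    landmark_names: tuple[str, ...]
    regions: tuple[str, ...]
    coords: np.ndarray  # (K, 3), mm
    unit: str = "cranium"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    def region_indices(self, tag: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.regions) == tag)
        if idx.size == 0:
            raise KeyError(f"template has no region {tag!r}")
        return idx

    @property
    def region_tags(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.regions:
            seen.setdefault(r, None)
        return list(seen)


@dataclass(frozen=True)
class EffectSpec:
    """Parametric regional displacement field for one genotype.

    ``region_scale`` maps a region tag to an isotropic factor applied about
    the region centroid (1.0 = no effect, <1 contraction / hypoplasia,
    >1 expansion). ``axis_scale`` maps a region tag to per-axis
    (x, y, z) factors for anisotropic effects such as mediolateral widening.
    Empty maps describe the null (no-effect) genotype.
    """

    region_scale: dict[str, float] = field(default_factory=dict)
    axis_scale: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    label: str = "affected"

    def __post_init__(self) -> None:
        for tag, f in self.region_scale.items():
            if not f > 0:
                raise ValueError(f"region_scale[{tag!r}] must be > 0, got {f}")
        for tag, fs in self.axis_scale.items():
            if len(fs) != 3 or not all(f > 0 for f in fs):
                raise ValueError(f"axis_scale[{tag!r}] must be three positive factors")

    @property
    def is_null(self) -> bool:
        return not self.region_scale and not self.axis_scale


@dataclass(frozen=True)
class NuisanceSpec:
    """Per-specimen rigid motion + scale jitter ranges (pose nuisance)."""

    rotation_deg: float = 0.0          # max rotation angle about a random axis
    translation_mm: float = 0.0        # max |translation| per axis
    scale_range: tuple[float, float] = (1.0, 1.0)  # uniform size jitter

    def __post_init__(self) -> None:
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError("scale_range must satisfy 0 < lo <= hi")
        if self.rotation_deg < 0 or self.translation_mm < 0:
            raise ValueError("rotation and translation ranges must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a two-group cohort (control vs affected genotype)."""

    template: Template
    effect: EffectSpec = field(default_factory=EffectSpec)
    n_control: int = 10
    n_affected: int = 10
    noise_sd: float = 0.05  # mm, isotropic per coordinate
    nuisance: NuisanceSpec | None = None
    seed: int = 0
    control_label: str = "WT"

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_affected < 2:
            raise ValueError("need at least 2 specimens per group")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def build_template(
    n_landmarks: int,
    regions: Sequence[tuple[str, int]],
    seed: int,
    unit: str = "cranium",
    semi_axes: tuple[float, float, float] = DEFAULT_SEMI_AXES,
) -> Template:
    """Draw a deterministic template on a half-ellipsoid "skull" surface.

    Landmarks are sampled on the upper (z >= 0) half of an ellipsoid with
    the given semi-axes, sorted front-to-back, and region tags are assigned
    to contiguous anteroposterior sectors in the order given. The centroid
    is translated exactly to the origin.
    """
    counts = [c for _, c in regions]
    if sum(counts) != n_landmarks:
        raise ValueError(
            f"region counts sum to {sum(counts)}, expected n_landmarks={n_landmarks}"
        )
    if n_landmarks < 4:
        raise ValueError("need n_landmarks >= 4")
    rng = np.random.default_rng(seed)
    # dense candidate cloud on the upper (z >= 0) half of the ellipsoid,
    # then greedy farthest-point selection: landmark protocols place
    # well-separated points spread over the whole structure, and REDs on
    # near-coincident landmarks would be dominated by digitization noise.
    n_candidates = max(500, 40 * n_landmarks)
    v = rng.normal(size=(n_candidates, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    v[:, 2] = np.abs(v[:, 2])
    candidates = np.asarray(semi_axes) * v
    chosen = [int(np.argmax(candidates[:, 0]))]  # start at the front
    dist_to_set = np.linalg.norm(candidates - candidates[chosen[0]], axis=1)
    for _ in range(n_landmarks - 1):
        nxt = int(np.argmax(dist_to_set))
        chosen.append(nxt)
        dist_to_set = np.minimum(
            dist_to_set, np.linalg.norm(candidates - candidates[nxt], axis=1)
        )
    coords = candidates[chosen]
    coords = coords[np.argsort(-coords[:, 0])]  # front (large x) to back
    coords -= coords.mean(axis=0)

    names: list[str] = []
    tags: list[str] = []
    for tag, count in regions:
        for i in range(count):
            names.append(f"{tag}_{i + 1:02d}")
            tags.append(tag)
    return Template(
        landmark_names=tuple(names),
        regions=tuple(tags),
        coords=coords,
        unit=unit,
        seed=seed,
    )


def desk_template(seed: int = 0, unit: str = "cranium") -> Template:
    """The package's default small study template: K=12, 3 regions of 4."""
    return build_template(12, DESK_REGIONS, seed=seed, unit=unit)


def apply_effect(template: Template, effect: EffectSpec) -> Template:
    """Deform a template by the regional displacement field of an effect.

    Each affected region is scaled about its own centroid (isotropic
    ``region_scale`` first, then per-axis ``axis_scale``), so a contraction
    mimics local hypoplasia without moving the rest of the anatomy; rows of
    untouched regions are copied bit-identically.
    """
    for tag in list(effect.region_scale) + list(effect.axis_scale):
        template.region_indices(tag)  # raises KeyError on unknown region
    coords = template.coords.copy()
    for tag, factor in effect.region_scale.items():
        idx = template.region_indices(tag)
        center = coords[idx].mean(axis=0)
        coords[idx] = center + factor * (coords[idx] - center)
    for tag, factors in effect.axis_scale.items():
        idx = template.region_indices(tag)
        center = coords[idx].mean(axis=0)
        coords[idx] = center + np.asarray(factors, dtype=float) * (coords[idx] - center)
    return Template(
        landmark_names=template.landmark_names,
        regions=template.regions,
        coords=coords,
        unit=template.unit,
        seed=template.seed,
    )


def _specimen_rng(master_seed: int, group_index: int, specimen_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(master_seed, spawn_key=(group_index, specimen_index))
    return np.random.default_rng(ss)


def _nuisance_transform(coords: np.ndarray, nuisance: NuisanceSpec, rng: np.random.Generator) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, nuisance.rotation_deg))
    rot = Rotation.from_rotvec(angle * axis).as_matrix()
    translation = rng.uniform(-nuisance.translation_mm, nuisance.translation_mm, size=3)
    scale = rng.uniform(*nuisance.scale_range)
    return scale * coords @ rot.T + translation


def sample_cohort(spec: CohortSpec) -> SpecimenSet:
    """Sample a two-group cohort from a :class:`CohortSpec`.

    Controls are template + iid N(0, noise_sd^2) per coordinate; the
    affected group uses ``apply_effect(template, effect)`` as its mean with
    the same noise model. Fully reproducible from ``spec.seed``.
    """
    bases = {
        0: (spec.control_label, spec.template.coords),
        1: (spec.effect.label, apply_effect(spec.template, spec.effect).coords),
    }
    sizes = {0: spec.n_control, 1: spec.n_affected}
    configurations = []
    for group_index in (0, 1):
        label, base = bases[group_index]
        for i in range(sizes[group_index]):
            rng = _specimen_rng(spec.seed, group_index, i)
            coords = base + rng.normal(0.0, spec.noise_sd, size=base.shape)
            if spec.nuisance is not None:
                coords = _nuisance_transform(coords, spec.nuisance, rng)
            configurations.append(
                LandmarkConfiguration(
                    specimen_id=f"{label}_{i + 1:02d}",
                    group=label,
                    unit=spec.template.unit,
                    landmark_names=spec.template.landmark_names,
                    regions=spec.template.regions,
                    coords=coords,
                )
            )
    return SpecimenSet.from_configurations(configurations)


# ---------------------------------------------------------------------------
# CohortSpec (de)serialization — YAML mirror of the dataclasses
# ---------------------------------------------------------------------------

def cohort_spec_to_dict(spec: CohortSpec) -> dict:
    d: dict = {
        "template": {
            "landmark_names": list(spec.template.landmark_names),
            "regions": list(spec.template.regions),
            "coords": [[float(v) for v in row] for row in spec.template.coords],
            "unit": spec.template.unit,
            "seed": spec.template.seed,
        },
        "effect": {
            "region_scale": {k: float(v) for k, v in spec.effect.region_scale.items()},
            "axis_scale": {k: [float(x) for x in v] for k, v in spec.effect.axis_scale.items()},
            "label": spec.effect.label,
        },
        "n_control": spec.n_control,
        "n_affected": spec.n_affected,
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "control_label": spec.control_label,
    }
    if spec.nuisance is not None:
        d["nuisance"] = {
            "rotation_deg": spec.nuisance.rotation_deg,
            "translation_mm": spec.nuisance.translation_mm,
            "scale_range": list(spec.nuisance.scale_range),
        }
    return d


def cohort_spec_from_dict(d: dict) -> CohortSpec:
    t = d["template"]
    template = Template(
        landmark_names=tuple(t["landmark_names"]),
        regions=tuple(t["regions"]),
        coords=np.asarray(t["coords"], dtype=float),
        unit=t.get("unit", "cranium"),
        seed=int(t.get("seed", 0)),
    )
    e = d.get("effect", {})
    effect = EffectSpec(
        region_scale={k: float(v) for k, v in e.get("region_scale", {}).items()},
        axis_scale={k: tuple(v) for k, v in e.get("axis_scale", {}).items()},
        label=e.get("label", "affected"),
    )
    nuisance = None
    if "nuisance" in d and d["nuisance"] is not None:
        n = d["nuisance"]
        nuisance = NuisanceSpec(
            rotation_deg=float(n.get("rotation_deg", 0.0)),
            translation_mm=float(n.get("translation_mm", 0.0)),
            scale_range=tuple(n.get("scale_range", (1.0, 1.0))),
        )
    return CohortSpec(
        template=template,
        effect=effect,
        n_control=int(d.get("n_control", 10)),
        n_affected=int(d.get("n_affected", 10)),
        noise_sd=float(d.get("noise_sd", 0.05)),
        nuisance=nuisance,
        seed=int(d.get("seed", 0)),
        control_label=d.get("control_label", "WT"),
    )


def save_cohort_spec(spec: CohortSpec, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cohort_spec_to_dict(spec), sort_keys=False), encoding="utf-8")
    return path


def load_cohort_spec(path: str | Path) -> CohortSpec:
    with open(path, "r", encoding="utf-8") as fh:
        return cohort_spec_from_dict(yaml.safe_load(fh))
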