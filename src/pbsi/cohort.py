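"""Synthetic multi-site, multi-group morphometric cohorts.

Generates cohorts with the statistical structure the similarity analysis
assumes: a shared inter-regional template profile per modality, additive age
and sex effects, and subject-level idiosyncratic Gaussian dispersion — the
heterogeneity knob.  Larger within-group dispersion scrambles subjects' rank
profiles relative to one another and therefore lowers within-group PBSI.

The noise model is deliberately minimal: Gaussian, independent across
regions after the shared template.  Volumes stay positive by construction
(template >> noise) rather than truncation, to avoid distorting ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from pbsi.io import CT, SV, MorphometrySchema, MorphometryTable, RegionSet

# modality base level and unit spread of the template across regions;
# `between_region_sd` scales the spread, keeping SV >> its noise
_BASE = {CT: 2.5, SV: 4000.0}
_SPREAD = {CT: 1.0, SV: 400.0}

SEXES = ("F", "M")
REFERENCE_SEX = "F"


def _as_group_map(value, groups: Sequence[str], name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = [g for g in groups if g not in value]
        if missing:
            raise ValueError(f"{name} missing groups: {missing}")
        return {g: float(value[g]) for g in groups}
    return {g: float(value) for g in groups}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort.

    Parameters
    ----------
    n_per_group
        Subjects per (group, site) cell: an int applied to every cell, or a
        mapping ``{(group, site): n}``.
    groups, sites
        Stratum labels.
    n_ct_regions, n_sv_regions
        Region counts per modality (>= 2 each; 64/18 by default).
    between_region_sd
        Scale of the template's spread across regions (unit spread per
        modality times this factor).
    within_group_dispersion
        Per-group standard deviation of the subject-level idiosyncratic
        noise, in CT units; a scalar applies to all groups.
    age_range
        Uniform sampling range for age in years.
    age_effect, sex_effect
        Per-region additive effects: scalars broadcast over regions, or
        mappings ``{"CT": vector, "SV": vector}``.  Age enters centred at
        the midpoint of ``age_range``; the sex offset is added for the
        reference sex (``F``).
    template_profile
        Optional explicit ``{"CT": vector, "SV": vector}`` of region means;
        drawn from the seed when omitted.
    seed
        Master seed; the cohort is a pure function of the spec.
    """

    n_per_group: int | Mapping[tuple[str, str], int] = 40
    groups: tuple[str, ...] = ("control", "patient")
    sites: tuple[str, ...] = ("siteA",)
    n_ct_regions: int = 64
    n_sv_regions: int = 18
    between_region_sd: float = 1.0
    within_group_dispersion: float | Mapping[str, float] = 0.5
    age_range: tuple[float, float] = (18.0, 65.0)
    age_effect: float | Mapping[str, np.ndarray] = 0.0
    sex_effect: float | Mapping[str, np.ndarray] = 0.0
    template_profile: Mapping[str, np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ct_regions < 2 or self.n_sv_regions < 2:
            raise ValueError("need >= 2 regions per modality (Spearman needs >= 2 ranks)")
        if not self.groups or not self.sites:
            raise ValueError("groups and sites must be non-empty")
        for (g, s), n in self.cell_sizes().items():
            if n <= 0:
                raise ValueError(f"non-positive n_per_group for cell ({g}, {s}): {n}")
        for g, d in self.dispersion_map().items():
            if d < 0:
                raise ValueError(f"negative within_group_dispersion for group {g!r}: {d}")
        if self.template_profile is not None:
            for mod, n in ((CT, self.n_ct_regions), (SV, self.n_sv_regions)):
                tpl = np.asarray(self.template_profile[mod], dtype=float)
                if tpl.shape != (n,):
                    raise ValueError(
                        f"template_profile[{mod}] has length {tpl.size}, expected {n}"
                    )

    def cell_sizes(self) -> dict[tuple[str, str], int]:
        """Cell -> subject count.  A mapping may omit cells entirely (a group
        absent at a site), but every listed count must be positive."""
        if isinstance(self.n_per_group, Mapping):
            out = {}
            for (g, s), n in self.n_per_group.items():
                if g not in self.groups or s not in self.sites:
                    raise ValueError(f"n_per_group references unknown cell ({g}, {s})")
                out[(g, s)] = int(n)
            if not out:
                raise ValueError("n_per_group mapping is empty")
            return out
        return {(g, s): int(self.n_per_group) for g in self.groups for s in self.sites}

    def dispersion_map(self) -> dict[str, float]:
        return _as_group_map(self.within_group_dispersion, self.groups, "within_group_dispersion")

    def region_counts(self) -> dict[str, int]:
        return {CT: self.n_ct_regions, SV: self.n_sv_regions}

    def schema(self) -> MorphometrySchema:
        ct = tuple(f"region{i:03d}" for i in range(self.n_ct_regions))
        sv = tuple(f"region{i:03d}" for i in range(self.n_sv_regions))
        return MorphometrySchema(ct=RegionSet(CT, ct), sv=RegionSet(SV, sv))

    def _effect_vector(self, which: str, modality: str) -> np.ndarray:
        value = self.age_effect if which == "age" else self.sex_effect
        n = self.region_counts()[modality]
        if isinstance(value, Mapping):
            vec = np.asarray(value[modality], dtype=float)
            if vec.shape != (n,):
                raise ValueError(f"{which}_effect[{modality}] has length {vec.size}, expected {n}")
            return vec
        return np.full(n, float(value))

    def templates(self) -> dict[str, np.ndarray]:
        """Region-level population means per modality (seed-deterministic)."""
        if self.template_profile is not None:
            return {m: np.asarray(self.template_profile[m], dtype=float) for m in (CT, SV)}
        rng = np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(0,)))
        out = {}
        for mod, n in ((CT, self.n_ct_regions), (SV, self.n_sv_regions)):
            out[mod] = _BASE[mod] + self.between_region_sd * _SPREAD[mod] * rng.standard_normal(n)
        return out


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth used to make it."""

    table: MorphometryTable
    spec: CohortSpec
    #: per-subject expected values (template + covariate effects, no noise),
    #: same region columns as the table — lets tests rescale noise exactly
    deterministic: pd.DataFrame = field(repr=False, default=None)
    #: realized per-subject noise scale (the group dispersion)
    noise_scale: pd.Series = field(repr=False, default=None)

    def truth(self) -> dict:
        """Sidecar-serializable ground-truth summary."""
        return {
            "seed": self.spec.seed,
            "groups": list(self.spec.groups),
            "sites": list(self.spec.sites),
            "n_ct_regions": self.spec.n_ct_regions,
            "n_sv_regions": self.spec.n_sv_regions,
            "dispersion": self.spec.dispersion_map(),
            "cell_sizes": {f"{g}/{s}": n for (g, s), n in self.spec.cell_sizes().items()},
        }


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort deterministically from ``spec``.

    For subject *i* in group *g*::

        measures_i = template
                     + age_effect * (age_i - mid(age_range))
                     + sex_effect * 1[sex_i == "F"]
                     + dispersion_g * eps_i,   eps_i ~ iid N(0, 1) per region

    Ages are uniform on ``age_range``; sexes alternate within each cell so
    groups are balanced.  One pseudo-random stream per subject, split from
    the master seed by global subject index, so enlarging the cohort never
    perturbs existing subjects.
    """
    templates = spec.templates()
    schema = spec.schema()
    dispersion = spec.dispersion_map()
    age_mid = 0.5 * (spec.age_range[0] + spec.age_range[1])
    effects = {
        mod: (spec._effect_vector("age", mod), spec._effect_vector("sex", mod))
        for mod in (CT, SV)
    }

    rows: list[dict] = []
    det_rows: list[dict] = []
    scales: list[float] = []
    idx = 0
    for (group, site), n_cell in spec.cell_sizes().items():
        for k in range(n_cell):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=spec.seed, spawn_key=(1, idx))
            )
            age = rng.uniform(*spec.age_range)
            sex = SEXES[k % 2]
            row: dict = {
                "subject_id": f"S{idx:05d}",
                "group": group,
                "site": site,
                "sex": sex,
                "age": age,
            }
            det_row = dict(row)
            for mod in (CT, SV):
                age_vec, sex_vec = effects[mod]
                mean = (
                    templates[mod]
                    + age_vec * (age - age_mid)
                    + sex_vec * (1.0 if sex == REFERENCE_SEX else 0.0)
                )
                eps = rng.standard_normal(len(mean))
                values = mean + dispersion[group] * eps
                for col, m, v in zip(schema.region_set(mod).columns, mean, values):
                    row[col] = v
                    det_row[col] = m
            rows.append(row)
            det_rows.append(det_row)
            scales.append(dispersion[group])
            idx += 1

    data = pd.DataFrame(rows)
    det = pd.DataFrame(det_rows)
    region_cols = schema.region_columns
    sv_cols = schema.sv.columns
    if (data[sv_cols].to_numpy() <= 0).any():
        raise ValueError(
            "generated non-positive volume; reduce dispersion or raise the SV template"
        )
    if not np.isfinite(data[region_cols].to_numpy()).all():
        raise ValueError("generated non-finite measure")
    table = MorphometryTable(data=data, schema=schema)
    return SyntheticCohort(
        table=table,
        spec=spec,
        deterministic=det,
        noise_scale=pd.Series(scales, index=data["subject_id"].to_numpy()),
    )


def inject_dominant_region(
    cohort: SyntheticCohort, region_column: str, boost: float
) -> SyntheticCohort:
    """Scale one region's idiosyncratic noise by ``boost`` for all subjects.

    Creates a known dominant contributor for leave-one-out tests: the
    region's observed values become ``deterministic + boost * residual``.
    All other columns are unchanged.  ``boost = 1`` is the identity.
    """
    if region_column not in cohort.table.schema.region_columns:
        raise KeyError(f"unknown region column {region_column!r}")
    data = cohort.table.data.copy()
    det = cohort.deterministic[region_column].to_numpy()
    obs = data[region_column].to_numpy()
    data[region_column] = det + float(boost) * (obs - det)
    table = MorphometryTable(data=data, schema=cohort.table.schema)
    return replace(cohort, table=table)
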