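"""Synthetic psychometric cohort generation.

The study cohort this package analyses is a wide table: one row per child,
twenty wave-1 predictors (child temperament, emotion, psychopathic traits,
prior conduct problems, parenting, and parent characteristics) plus the
wave-2 conduct-problems outcome ``CP.2``, every column on a common 1–5
scale.  Because the raw longitudinal data are not publicly deposited, this
module generates cohorts with the statistical structure the downstream
analysis assumes:

* truncated-normal marginals moment-matched to published per-variable
  means and standard deviations;
* a single shared latent risk factor plus within-block correlation bumps
  (risk-loaded variables load positively, protective ones negatively);
* strong year-to-year stability of conduct problems, expressed as a target
  sample correlation between ``CP.1`` and ``CP.2``;
* an optional planted non-linear interaction: children exceeding cutoffs
  on every variable of an interaction set receive an additive shift on
  ``CP.2`` before final moment matching;
* missing-completely-at-random cell deletion for testing complete-case
  filtering.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

__all__ = [
    "BLOCKS",
    "VariableSpec",
    "CohortSpec",
    "CohortSpecError",
    "default_variables",
    "default_cohort_spec",
    "generate_cohort",
    "inject_missingness",
    "read_cohort_csv",
    "write_cohort_csv",
]

BLOCKS = (
    "child_temperament",
    "child_emotion",
    "child_psychopathic",
    "child_cp",
    "parenting",
    "parent_characteristics",
)

OUTCOME = "CP.2"


class CohortSpecError(ValueError):
    """Raised when a cohort specification violates its invariants."""


@dataclass(frozen=True)
class VariableSpec:
    """Target marginal moments for one cohort variable on the 1–5 scale."""

    name: str
    target_mean: float
    target_sd: float
    block: str

    def validate(self) -> None:
        if not (1.0 <= self.target_mean <= 5.0):
            raise CohortSpecError(
                f"target_mean for {self.name!r} must lie in [1, 5], got {self.target_mean}"
            )
        if not self.target_sd > 0:
            raise CohortSpecError(
                f"target_sd for {self.name!r} must be positive, got {self.target_sd}"
            )
        if self.block not in BLOCKS:
            raise CohortSpecError(f"unknown block {self.block!r} for {self.name!r}")


def default_variables() -> list[VariableSpec]:
    """The 20 predictors plus CP.2 with published marginal moments."""
    rows = [
        ("TEMP_FOC.1", 3.60, 1.06, "child_temperament"),
        ("TEMP_INHIB.1", 3.56, 0.68, "child_temperament"),
        ("REG.1", 4.35, 0.52, "child_emotion"),
        ("LAB_NEG.1", 1.86, 0.48, "child_emotion"),
        ("EMP_AF.1", 4.12, 0.75, "child_emotion"),
        ("EMP_COG.1", 4.28, 0.83, "child_emotion"),
        ("GD.1", 1.44, 0.60, "child_psychopathic"),
        ("INS.1", 2.30, 0.79, "child_psychopathic"),
        ("CU.1", 1.30, 0.51, "child_psychopathic"),
        ("CP.1", 1.43, 0.44, "child_cp"),
        ("CONFLICT.1", 1.62, 0.66, "parenting"),
        ("OVERREACT.1", 2.44, 0.61, "parenting"),
        ("LAXNESS.1", 1.96, 0.57, "parenting"),
        ("WARMTH.1", 4.62, 0.44, "parenting"),
        ("STRESS_PAR.1", 1.73, 0.68, "parenting"),
        ("PHQ_ANS.1", 1.94, 0.90, "parent_characteristics"),
        ("PHQ_DEP.1", 1.79, 0.83, "parent_characteristics"),
        ("STRESS_PERC.1", 2.24, 0.68, "parent_characteristics"),
        ("SUPPORT_E.1", 4.50, 0.80, "parent_characteristics"),
        ("SUPPORT_I.1", 4.60, 0.67, "parent_characteristics"),
        (OUTCOME, 1.36, 0.41, "child_cp"),
    ]
    return [VariableSpec(*r) for r in rows]


# Loadings on the shared risk factor.  Risk-loaded variables positive,
# protective ones negative; magnitudes are moderate so that individual-block
# variables dominate prediction without dictating it.
_DEFAULT_LOADINGS: dict[str, float] = {
    "TEMP_FOC.1": -0.40,
    "TEMP_INHIB.1": -0.45,
    "REG.1": -0.45,
    "LAB_NEG.1": 0.50,
    "EMP_AF.1": -0.25,
    "EMP_COG.1": -0.30,
    "GD.1": 0.55,
    "INS.1": 0.50,
    "CU.1": 0.50,
    "CP.1": 0.60,
    "CONFLICT.1": 0.45,
    "OVERREACT.1": 0.35,
    "LAXNESS.1": 0.25,
    "WARMTH.1": -0.35,
    "STRESS_PAR.1": 0.35,
    "PHQ_ANS.1": 0.30,
    "PHQ_DEP.1": 0.30,
    "STRESS_PERC.1": 0.30,
    "SUPPORT_E.1": -0.20,
    "SUPPORT_I.1": -0.20,
    OUTCOME: 0.45,
}

_DEFAULT_BLOCK_LOADINGS: dict[str, float] = {b: 0.30 for b in BLOCKS}


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for one synthetic cohort draw."""

    variables: tuple[VariableSpec, ...] = field(
        default_factory=lambda: tuple(default_variables())
    )
    latent_loadings: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LOADINGS)
    )
    block_loadings: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BLOCK_LOADINGS)
    )
    stability_r: float = 0.8
    interaction_effect: float = 0.6
    interaction_set: tuple[tuple[str, float], ...] = (
        ("GD.1", 2.5),
        ("CONFLICT.1", 2.5),
    )
    missing_rate: float = 0.0
    n: int = 1095
    seed: int = 0

    def validate(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise CohortSpecError("variables: duplicate names in cohort spec")
        if OUTCOME not in names:
            raise CohortSpecError(f"variables: outcome column {OUTCOME!r} missing")
        for v in self.variables:
            v.validate()
        if not abs(self.stability_r) <= 1:
            raise CohortSpecError(
                f"stability_r must lie in [-1, 1], got {self.stability_r}"
            )
        for var, _cut in self.interaction_set:
            if var not in names:
                raise CohortSpecError(
                    f"interaction_set: variable {var!r} not in cohort variables"
                )
        if not (0 <= self.missing_rate < 1):
            raise CohortSpecError(
                f"missing_rate must lie in [0, 1), got {self.missing_rate}"
            )
        if self.n < 50:
            raise CohortSpecError(f"n must be at least 50, got {self.n}")

    @property
    def predictor_names(self) -> list[str]:
        return [v.name for v in self.variables if v.name != OUTCOME]

    @property
    def column_names(self) -> list[str]:
        return self.predictor_names + [OUTCOME]


def default_cohort_spec(**overrides) -> CohortSpec:
    """The default study conditions; keyword overrides patch single fields."""
    return replace(CohortSpec(), **overrides) if overrides else CohortSpec()


def _match_clip(latent: np.ndarray, mean: float, sd: float, n_iter: int = 40) -> np.ndarray:
    """Affinely map a latent sample so its [1,5]-clipped moments hit the target.

    Solves clip(a + b*z) having sample mean/SD (ddof=1) equal to the target by
    fixed-point iteration; with targets near the scale floor the truncation is
    substantial and a single affine pass would miss by far more than 5%.
    """
    z = (latent - latent.mean()) / latent.std(ddof=1)
    a, b = mean, sd
    y = np.clip(a + b * z, 1.0, 5.0)
    for _ in range(n_iter):
        m, s = y.mean(), y.std(ddof=1)
        if s == 0:
            break
        a += mean - m
        b *= sd / s
        y = np.clip(a + b * z, 1.0, 5.0)
    return y


def _interaction_mask(frame: pd.DataFrame, spec: CohortSpec) -> np.ndarray:
    mask = np.ones(len(frame), dtype=bool)
    for var, cut in spec.interaction_set:
        mask &= frame[var].to_numpy() > cut
    return mask


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort table from the latent-factor model.

    Predictors are ``loading × risk factor + block factor bump + noise``,
    clipped and moment-matched to their target marginals.  ``CP.2`` combines
    a stability-weighted component of the realised ``CP.1`` column, the
    shared factor, the planted interaction shift, and noise; when
    ``stability_r`` is non-zero its latent weight is calibrated by a root
    solve so that the *observed* corr(CP.1, CP.2) matches the target despite
    clipping attenuation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    risk = rng.standard_normal(n)
    block_factors = {b: rng.standard_normal(n) for b in BLOCKS}

    frame = pd.DataFrame(index=pd.RangeIndex(n, name="child_id"))
    var_by_name = {v.name: v for v in spec.variables}
    for v in spec.variables:
        if v.name == OUTCOME:
            continue
        lam = spec.latent_loadings.get(v.name, 0.0)
        lb = spec.block_loadings.get(v.block, 0.0) if lam != 0.0 else 0.0
        resid = np.sqrt(max(1.0 - lam * lam - lb * lb, 0.05))
        latent = lam * risk + lb * block_factors[v.block] + resid * rng.standard_normal(n)
        frame[v.name] = _match_clip(latent, v.target_mean, v.target_sd)

    out = var_by_name[OUTCOME]
    lam_out = spec.latent_loadings.get(OUTCOME, 0.0)
    noise = rng.standard_normal(n)
    cp1 = frame["CP.1"].to_numpy()
    zc = (cp1 - cp1.mean()) / cp1.std(ddof=1)
    mask = _interaction_mask(frame, spec)

    def build(r_lat: float) -> np.ndarray:
        resid = np.sqrt(max(1.0 - r_lat * r_lat - lam_out * lam_out, 0.05))
        raw = r_lat * zc + lam_out * risk + resid * noise
        raw = (raw - raw.mean()) / raw.std(ddof=1)
        y = out.target_mean + out.target_sd * raw
        if spec.interaction_effect != 0.0:
            y = y + spec.interaction_effect * mask
        return _match_clip(y, out.target_mean, out.target_sd)

    if spec.stability_r == 0.0:
        cp2 = build(0.0)
    else:
        target = spec.stability_r

        def gap(r_lat: float) -> float:
            y = build(r_lat)
            return float(np.corrcoef(cp1, y)[0, 1]) - target

        lo, hi = -0.999, 0.999
        if gap(hi) < 0:  # target unreachable after clipping; saturate
            cp2 = build(hi)
        elif gap(lo) > 0:
            cp2 = build(lo)
        else:
            r_star = brentq(gap, lo, hi, xtol=1e-4)
            cp2 = build(r_star)

    frame[OUTCOME] = cp2
    return frame


def inject_missingness(table: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Blank each cell independently with probability ``rate`` (MCAR)."""
    if not (0 <= rate < 1):
        raise CohortSpecError(f"missingness rate must lie in [0, 1), got {rate}")
    if rate == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    mask = rng.random(table.shape) < rate
    arr = table.to_numpy(dtype=float).copy()
    arr[mask] = np.nan
    return pd.DataFrame(arr, index=table.index, columns=table.columns)


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Write the cohort as CSV; missing cells become empty fields."""
    table.to_csv(path, index=True, index_label=table.index.name or "child_id")


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def spec_to_yaml(spec: CohortSpec, path=None) -> str:
    """Serialize a cohort spec to YAML (returned; also written when path given)."""
    payload = {
        "variables": [
            {
                "name": v.name,
                "target_mean": v.target_mean,
                "target_sd": v.target_sd,
                "block": v.block,
            }
            for v in spec.variables
        ],
        "latent_loadings": dict(spec.latent_loadings),
        "block_loadings": dict(spec.block_loadings),
        "stability_r": spec.stability_r,
        "interaction_effect": spec.interaction_effect,
        "interaction_set": [[v, c] for v, c in spec.interaction_set],
        "missing_rate": spec.missing_rate,
        "n": spec.n,
        "seed": spec.seed,
    }
    text = yaml.safe_dump(payload, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def spec_from_yaml(source) -> CohortSpec:
    """Load a cohort spec from a YAML string or file path."""
    if hasattr(source, "read"):
        payload = yaml.safe_load(source.read())
    else:
        text = str(source)
        if "\n" not in text and text.endswith((".yml", ".yaml")):
            with open(text) as fh:
                payload = yaml.safe_load(fh)
        else:
            payload = yaml.safe_load(text)
    spec = CohortSpec(
        variables=tuple(
            VariableSpec(
                name=v["name"],
                target_mean=float(v["target_mean"]),
                target_sd=float(v["target_sd"]),
                block=v["block"],
            )
            for v in payload["variables"]
        ),
        latent_loadings={k: float(v) for k, v in payload["latent_loadings"].items()},
        block_loadings={k: float(v) for k, v in payload["block_loadings"].items()},
        stability_r=float(payload["stability_r"]),
        interaction_effect=float(payload["interaction_effect"]),
        interaction_set=tuple((v, float(c)) for v, c in payload["interaction_set"]),
        missing_rate=float(payload["missing_rate"]),
        n=int(payload["n"]),
        seed=int(payload["seed"]),
    )
    spec.validate()
    return spec
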