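"""Seeded synthetic humanized-mouse cohorts with compositional flow-cytometry structure.

The generator emulates a cohort of immunodeficient mice engrafted with human
cord-blood CD34+ stem cells, half of which receive an immunization (induced
dendritic cells), measured post-mortem by flow cytometry in up to six
tissues: peripheral blood (PB), bone marrow (BM), spleen (SPL), thymus
(THY), combined peripheral + mesenteric lymph nodes (PLN_MLN) and mesenteric
lymph nodes alone (MLN).

Per mouse and tissue the generator draws

* a human-CD45+ engraftment percentage (beta),
* a lineage composition within huCD45 — B cells (CD19), T cells (CD3),
  monocytes CD14 (progenitors CD34 in BM) and an "other" remainder —
  from a Dirichlet, closing to 100%,
* a CD4/CD8 split of the T-cell compartment (beta),
* naive / central-memory / effector-memory / terminal-effector (N/CM/EM/TE)
  compositions within CD4 and within CD8 (Dirichlet, closing to 100%),
* for the thymus, a DN/DP/CD4SP/CD8SP developmental composition plus the
  TCRab+ fraction of CD3 and the CD4:CD8 single-positive ratio,
* a total human-cell count (negative binomial) from which gated subset
  counts are derived by rounding, so counts and frequencies stay consistent.

Immunization effects are planted as additive shifts on the log scale of the
Dirichlet concentrations (equivalently, log-odds shifts of the expected
composition), optionally amplified for females via a per-tissue sex
modifier.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from immunosig.errors import ConfigError, FeatureDisabledError

TISSUES = ("PB", "BM", "SPL", "THY", "PLN_MLN", "MLN")
NONTHYMIC = ("PB", "BM", "SPL", "PLN_MLN", "MLN")
SUBSET_STAGES = ("N", "CM", "EM", "TE")
THY_COMPARTMENTS = ("DN", "DP", "CD4SP", "CD8SP")

#: tissues for which absolute counts are generated (PB is frequency-only)
COUNT_TISSUES = ("BM", "SPL", "THY", "PLN_MLN", "MLN")


def lineage_markers(tissue: str) -> tuple[str, str, str, str]:
    """Names of the four lineage compartments within huCD45 for a tissue.

    The myeloid slot is CD14 everywhere except bone marrow, where the CD34+
    progenitor compartment is gated instead.
    """
    myeloid = "CD34" if tissue == "BM" else "CD14"
    return ("CD19", "CD3", myeloid, "otherCD45")


@dataclass
class MouseRecord:
    """Identity and design factors of one animal."""

    mouse_id: str
    sex: str  # "F" | "M"
    group: str  # "control" | "immunized"
    cb_unit: str  # cord-blood unit label, e.g. "CB1"

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ConfigError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.group not in ("control", "immunized"):
            raise ConfigError(f"group must be 'control' or 'immunized', got {self.group!r}")


@dataclass
class TissueMeasurement:
    """One gated readout for one mouse in one tissue."""

    mouse_id: str
    tissue: str
    marker: str
    value_type: str  # "frequency_percent" | "count" | "concentration"
    value: float
    censored: bool = False


@dataclass
class CohortDataset:
    """A cohort: mouse roster plus long-format measurements."""

    mice: list[MouseRecord]
    measurements: list[TissueMeasurement]
    provenance: str = ""

    def validate(self) -> None:
        ids = [m.mouse_id for m in self.mice]
        if len(set(ids)) != len(ids):
            raise ConfigError("mouse_id values are not unique within the cohort")
        known = set(ids)
        seen: set[tuple[str, str, str, str]] = set()
        for meas in self.measurements:
            if meas.mouse_id not in known:
                raise ConfigError(f"measurement references unknown mouse_id {meas.mouse_id!r}")
            key = (meas.mouse_id, meas.tissue, meas.marker, meas.value_type)
            if key in seen:
                raise ConfigError(f"duplicate measurement key {key}")
            seen.add(key)

    def mouse(self, mouse_id: str) -> MouseRecord:
        for m in self.mice:
            if m.mouse_id == mouse_id:
                return m
        raise KeyError(mouse_id)


def _default_baseline() -> dict:
    """Per-tissue Dirichlet concentrations for the compositional blocks.

    Concentration totals around 40-60 give coefficient-of-variation levels
    typical of gated frequencies across individual humanized mice.
    """
    lineage = {
        # (CD19, CD3, CD14|CD34, otherCD45) — B-cell rich blood/BM, T-rich
        # lymphoid organs
        "PB": np.array([24.0, 18.0, 6.0, 12.0]),
        "BM": np.array([30.0, 6.0, 9.0, 15.0]),
        "SPL": np.array([21.0, 24.0, 3.0, 12.0]),
        "PLN_MLN": np.array([12.0, 33.0, 1.5, 13.5]),
        "MLN": np.array([12.0, 33.0, 1.5, 13.5]),
    }
    cd4_subsets = {t: np.array([25.0, 10.0, 10.0, 5.0]) for t in NONTHYMIC}
    cd8_subsets = {t: np.array([27.5, 7.5, 10.0, 5.0]) for t in NONTHYMIC}
    baseline = {
        t: {
            "lineage": lineage[t],
            "cd4_subsets": cd4_subsets[t],
            "cd8_subsets": cd8_subsets[t],
        }
        for t in NONTHYMIC
    }
    # DN / DP / CD4SP / CD8SP — double positives dominate a healthy thymus
    baseline["THY"] = {"thymocyte": np.array([5.0, 37.5, 5.0, 2.5])}
    return baseline


@dataclass
class CohortConfig:
    """Generator parameters for one synthetic cohort.

    ``effect_map[tissue][marker]`` holds additive log-odds shifts applied to
    the immunized group; ``sex_modifier[tissue]`` multiplies those shifts for
    female mice.  Frequencies are emitted as percentages (0-100).
    """

    n_control: int = 11
    n_immunized: int = 17
    female_fraction: float = 0.5
    tissues: tuple[str, ...] = TISSUES
    tissue_availability: dict = field(default_factory=dict)
    baseline_composition: dict = field(default_factory=_default_baseline)
    cd4_of_cd3_mean: float = 0.65
    cd4_split_concentration: float = 40.0
    cd45_level: dict = field(default_factory=dict)  # tissue -> (mean fraction, concentration)
    tcrab_level: tuple[float, float] = (0.85, 30.0)  # THY TCRab+/CD3
    effect_map: dict = field(default_factory=dict)
    sex_modifier: dict = field(default_factory=dict)
    count_model: dict = field(default_factory=dict)  # tissue -> (mean, dispersion)
    cytokine_model: Optional[dict] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_control < 0 or self.n_immunized < 0:
            raise ConfigError("n_control and n_immunized must be non-negative")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction must lie in [0, 1]")
        for t in self.tissues:
            if t not in TISSUES:
                raise ConfigError(f"tissues: unknown tissue code {t!r}")
        for t, p in self.tissue_availability.items():
            if t not in self.tissues:
                raise ConfigError(f"tissue_availability: {t!r} is not a declared tissue")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"tissue_availability[{t!r}] must lie in [0, 1]")
        for t, blocks in self.baseline_composition.items():
            for name, alpha in blocks.items():
                if np.any(np.asarray(alpha, dtype=float) <= 0):
                    raise ConfigError(
                        f"baseline_composition[{t!r}][{name!r}] must be strictly positive"
                    )
        if not 0.0 < self.cd4_of_cd3_mean < 1.0:
            raise ConfigError("cd4_of_cd3_mean must lie strictly inside (0, 1)")
        for t, markers in self.effect_map.items():
            if t not in self.tissues:
                raise ConfigError(f"effect_map: {t!r} is not a declared tissue")
            declared = set(tissue_marker_names(t))
            for m in markers:
                if m not in declared:
                    raise ConfigError(f"effect_map[{t!r}]: unknown marker {m!r}")
        for t, (mean, disp) in self.count_model.items():
            if mean <= 0 or disp <= 0:
                raise ConfigError(f"count_model[{t!r}] mean and dispersion must be positive")

    def config_hash(self) -> str:
        def enc(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, dict):
                return {str(k): enc(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        payload = json.dumps(enc(self.__dict__), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def tissue_marker_names(tissue: str) -> list[str]:
    """All frequency-marker names the generator emits for a tissue."""
    if tissue == "THY":
        # CD4_CD8_ratio is derived (CD4SP/CD8SP) at panel-building time
        return ["huCD45", "CD3", "CD4SP", "CD8SP", "DN", "DP", "TCRab_CD3"]
    names = ["huCD45", *lineage_markers(tissue), "CD4", "CD8"]
    names += [f"CD4_{s}" for s in SUBSET_STAGES]
    names += [f"CD8_{s}" for s in SUBSET_STAGES]
    return names


def default_config(seed: int = 0) -> CohortConfig:
    """The reference cohort: 11 control vs 17 immunized mice, six tissues.

    Tissue availability reproduces, in expectation, the per-tissue sample
    counts of the emulated study (thymus 27/28, PLN+MLN 19/28, MLN 21/28,
    SPL/BM/PB all 28).  The default effect map raises CD8 effector-memory
    and terminal-effector log-odds in spleen and lymph nodes of immunized
    mice, more strongly in females.
    """
    availability = {
        "PB": 1.0,
        "BM": 1.0,
        "SPL": 1.0,
        "THY": 27.0 / 28.0,
        "PLN_MLN": 19.0 / 28.0,
        "MLN": 21.0 / 28.0,
    }
    effect_map = {
        "SPL": {"CD8_EM": 0.9, "CD8_TE": 0.6, "CD4_EM": 0.4},
        "PLN_MLN": {"CD8_EM": 0.9, "CD8_TE": 0.6, "CD4_EM": 0.4},
        "MLN": {"CD8_EM": 0.5, "CD8_TE": 0.3},
        "PB": {"CD8_EM": 0.3},
    }
    sex_modifier = {"SPL": 1.6, "PLN_MLN": 1.6, "MLN": 1.3}
    count_model = {
        "BM": (3.0e5, 5.0),
        "SPL": (5.0e5, 5.0),
        "THY": (1.0e5, 4.0),
        "PLN_MLN": (2.0e5, 4.0),
        "MLN": (1.0e5, 4.0),
    }
    cd45_level = {
        "PB": (0.45, 20.0),
        "BM": (0.55, 20.0),
        "SPL": (0.60, 20.0),
        "THY": (0.90, 25.0),
        "PLN_MLN": (0.70, 20.0),
        "MLN": (0.70, 20.0),
    }
    return CohortConfig(
        tissue_availability=availability,
        effect_map=effect_map,
        sex_modifier=sex_modifier,
        count_model=count_model,
        cd45_level=cd45_level,
        seed=seed,
    )


def _beta_from_mean(rng: np.random.Generator, mean: float, conc: float) -> float:
    return float(rng.beta(mean * conc, (1.0 - mean) * conc))


def _logit_shift(mean: float, shift: float) -> float:
    lo = np.log(mean / (1.0 - mean)) + shift
    return float(1.0 / (1.0 + np.exp(-lo)))


def _shifted_alpha(alpha: np.ndarray, names: tuple[str, ...] | list[str],
                   shifts: dict, factor: float) -> np.ndarray:
    """Multiply targeted concentrations by exp(shift × factor).

    This moves the expected composition log-odds of the targeted component
    by approximately shift × factor while leaving total concentration (and
    hence within-group variability) comparable.
    """
    out = np.asarray(alpha, dtype=float).copy()
    for j, name in enumerate(names):
        delta = shifts.get(name)
        if delta:
            out[j] *= np.exp(delta * factor)
    return out


def dirichlet_expected_percent(alpha: np.ndarray) -> np.ndarray:
    """Analytic Dirichlet mean composition, as percentages."""
    alpha = np.asarray(alpha, dtype=float)
    return 100.0 * alpha / alpha.sum()


def _draw_tissue(rng: np.random.Generator, config: CohortConfig, mouse: MouseRecord,
                 tissue: str) -> list[TissueMeasurement]:
    immunized = mouse.group == "immunized"
    factor = config.sex_modifier.get(tissue, 1.0) if mouse.sex == "F" else 1.0
    shifts = config.effect_map.get(tissue, {}) if immunized else {}

    freqs: dict[str, float] = {}
    cd45_mean, cd45_conc = config.cd45_level.get(tissue, (0.5, 20.0))
    if "huCD45" in shifts:
        cd45_mean = _logit_shift(cd45_mean, shifts["huCD45"] * factor)
    freqs["huCD45"] = 100.0 * _beta_from_mean(rng, cd45_mean, cd45_conc)

    if tissue == "THY":
        alpha = _shifted_alpha(config.baseline_composition["THY"]["thymocyte"],
                               THY_COMPARTMENTS, shifts, factor)
        comp = 100.0 * rng.dirichlet(alpha)
        # close the four-part composition exactly
        comp[-1] = 100.0 - comp[:-1].sum()
        for name, v in zip(THY_COMPARTMENTS, comp):
            freqs[name] = float(v)
        freqs["CD3"] = float(freqs["CD4SP"] + freqs["CD8SP"]
                             + 0.9 * freqs["DP"] * rng.beta(20.0, 5.0))
        freqs["CD3"] = min(freqs["CD3"], 100.0)
        tcr_mean, tcr_conc = config.tcrab_level
        if "TCRab_CD3" in shifts:
            tcr_mean = _logit_shift(tcr_mean, shifts["TCRab_CD3"] * factor)
        freqs["TCRab_CD3"] = 100.0 * _beta_from_mean(rng, tcr_mean, tcr_conc)
    else:
        lin_names = lineage_markers(tissue)
        alpha = _shifted_alpha(config.baseline_composition[tissue]["lineage"],
                               lin_names, shifts, factor)
        comp = 100.0 * rng.dirichlet(alpha)
        comp[-1] = 100.0 - comp[:-1].sum()
        for name, v in zip(lin_names, comp):
            freqs[name] = float(v)
        cd4_mean = config.cd4_of_cd3_mean
        if "CD4" in shifts:
            cd4_mean = _logit_shift(cd4_mean, shifts["CD4"] * factor)
        p4 = _beta_from_mean(rng, cd4_mean, config.cd4_split_concentration)
        freqs["CD4"] = p4 * freqs["CD3"]
        freqs["CD8"] = freqs["CD3"] - freqs["CD4"]
        for lineage in ("CD4", "CD8"):
            key = f"{lineage.lower()}_subsets"
            names = [f"{lineage}_{s}" for s in SUBSET_STAGES]
            alpha = _shifted_alpha(config.baseline_composition[tissue][key],
                                   names, shifts, factor)
            sub = 100.0 * rng.dirichlet(alpha)
            sub[-1] = 100.0 - sub[:-1].sum()
            for name, v in zip(names, sub):
                freqs[name] = float(v)

    out = [
        TissueMeasurement(mouse.mouse_id, tissue, marker, "frequency_percent", value)
        for marker, value in freqs.items()
    ]

    if tissue in config.count_model and tissue in COUNT_TISSUES:
        mean, k = config.count_model[tissue]
        total = int(rng.negative_binomial(k, k / (k + mean)))
        counts: dict[str, int] = {}
        counts["huCD45"] = int(round(freqs["huCD45"] / 100.0 * total))
        if tissue == "THY":
            for name in ("CD3", *THY_COMPARTMENTS):
                counts[name] = int(round(freqs[name] / 100.0 * counts["huCD45"]))
        else:
            for name in (*lineage_markers(tissue), "CD4", "CD8"):
                counts[name] = int(round(freqs[name] / 100.0 * counts["huCD45"]))
            for lineage in ("CD4", "CD8"):
                for s in SUBSET_STAGES:
                    name = f"{lineage}_{s}"
                    counts[name] = int(round(freqs[name] / 100.0 * counts[lineage]))
        out += [
            TissueMeasurement(mouse.mouse_id, tissue, marker, "count", float(value))
            for marker, value in counts.items()
        ]
    return out


def generate_cohort(config: CohortConfig) -> CohortDataset:
    """Draw a full cohort; deterministic for a given config (incl. seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    mice: list[MouseRecord] = []
    idx = 0
    for group, n in (("control", config.n_control), ("immunized", config.n_immunized)):
        n_f = int(round(config.female_fraction * n))
        sexes = ["F"] * n_f + ["M"] * (n - n_f)
        rng.shuffle(sexes)
        for sex in sexes:
            idx += 1
            cb = f"CB{rng.integers(1, 4)}"
            mice.append(MouseRecord(f"M{idx:03d}", sex, group, cb))

    measurements: list[TissueMeasurement] = []
    for mouse in mice:
        for tissue in config.tissues:
            if rng.random() >= config.tissue_availability.get(tissue, 1.0):
                continue
            measurements.extend(_draw_tissue(rng, config, mouse, tissue))

    dataset = CohortDataset(
        mice=mice,
        measurements=measurements,
        provenance=f"synthetic seed={config.seed} config={config.config_hash()}",
    )
    dataset.validate()
    return dataset


def default_cytokine_model() -> dict:
    """A plasma multiplex-style analyte model with an immunization response."""
    return {
        "analytes": {
            "IFNg": (1.5, 0.8),
            "IL6": (2.0, 0.7),
            "IL10": (1.0, 0.6),
            "TNFa": (1.8, 0.7),
        },
        "group_shift": {"IFNg": np.log(2.5), "TNFa": np.log(1.5)},
        "sex_shift": {},
        "detection_limit": 1.0,
    }


def generate_cytokines(config: CohortConfig, mice: list[MouseRecord],
                       rng: Optional[np.random.Generator] = None) -> list[TissueMeasurement]:
    """Log-normal plasma analyte concentrations with group/sex shifts.

    Values below the model's detection limit are emitted with their drawn
    value but flagged censored, mirroring below-detection-limit reporting.
    """
    if config.cytokine_model is None:
        raise FeatureDisabledError("cytokine_model is not configured")
    model = config.cytokine_model
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x0C]))
    limit = model.get("detection_limit", 0.0)
    out = []
    for mouse in mice:
        for analyte, (mu, sd) in model["analytes"].items():
            shift = 0.0
            if mouse.group == "immunized":
                shift += model.get("group_shift", {}).get(analyte, 0.0)
            if mouse.sex == "F":
                shift += model.get("sex_shift", {}).get(analyte, 0.0)
            value = float(np.exp(rng.normal(mu + shift, sd)))
            out.append(TissueMeasurement(mouse.mouse_id, "PLASMA", analyte,
                                         "concentration", value,
                                         censored=value < limit))
    return out


def with_effects(config: CohortConfig, effect_map: dict,
                 sex_modifier: Optional[dict] = None) -> CohortConfig:
    """Copy of a config with the effect map (and optionally sex modifiers) replaced."""
    return replace(
        config,
        effect_map=effect_map,
        sex_modifier=config.sex_modifier if sex_modifier is None else sex_modifier,
    )


def simulate_correlation_pair(r_control: float, r_immunized: float,
                              n_per_group: int, seed: int = 0
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Bivariate-normal marker pair with group-dependent correlation.

    Returns (control, immunized) arrays of shape (n_per_group, 2) drawn
    with the requested Pearson correlations — the calibration input for
    differential-correlation signature classification (e.g. a sign-flipped
    pair, or a pair whose correlation is lost after immunization).
    """
    rng = np.random.default_rng(seed)
    out = []
    for r in (r_control, r_immunized):
        cov = np.array([[1.0, r], [r, 1.0]])
        out.append(rng.multivariate_normal(np.zeros(2), cov, size=n_per_group))
    return out[0], out[1]


def null_config(seed: int = 0, **overrides) -> CohortConfig:
    """Default cohort with every immunization effect removed (for calibration)."""
    cfg = replace(default_config(seed), effect_map={}, sex_modifier={})
    return replace(cfg, **overrides) if overrides else cfg
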