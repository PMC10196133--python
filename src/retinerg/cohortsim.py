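"""Synthetic cohorts with the statistical structure the analysis assumes.

The simulator emulates a cross-sectional two-genotype (WT vs HOM) study at
4, 6 and 14 months. Each endpoint is drawn Gaussian around a genotype×age
mean; a single per-animal latent severity factor ``s ~ N(0,1)`` couples
HOM α-synuclein abundance (positively) to outer-retinal structure and cone
bipolar function (negatively), inducing the negative α-SYN ↔ ONL and
α-SYN ↔ cone-P2 correlations the analysis is meant to detect. Human and
pSer129 α-SYN are exactly zero in wildtype animals (human-transgene model).

Endpoints can be materialized two ways:

* directly, as per-animal scalars (fast; used for power/calibration runs);
* as raw inputs — full ERG waveform families via :mod:`retinerg.ergsim` and
  en-face thickness grids — so the entire decompose → summarize → stats
  pipeline can be exercised end to end against known ground truth.

Ground truth (planted means, severity draws) is retained on the dataset for
recovery tests. All randomness flows from one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import blotquant, ergdecomp, ergsim, octthick, stats
from .errors import ConfigurationError, StageError

WT, HOM = "WT", "HOM"

ERG_ENDPOINTS = ("rod_rmp3", "rod_vmax", "cone_rmp3", "cone_vmax", "pstr")
LAYER_ENDPOINTS = octthick.LAYERS  # RNFL, GCIPL, INL, OPL, ONL
BLOT_ENDPOINTS = ("th", "mouse_asyn", "human_asyn", "pser129_asyn")
#: Abundances the wildtype does not express at all.
HOM_ONLY = ("human_asyn", "pser129_asyn")
ALL_ENDPOINTS = ERG_ENDPOINTS + LAYER_ENDPOINTS + BLOT_ENDPOINTS


@dataclass(frozen=True)
class StudyDesign:
    genotypes: tuple[str, str] = (WT, HOM)
    ages: tuple[float, ...] = (4.0, 6.0, 14.0)
    n_per_cell: int | Mapping[tuple[str, float], int] = 16
    sex_balance: bool = True

    def __post_init__(self) -> None:
        if list(self.ages) != sorted(self.ages):
            raise ConfigurationError("ages must be strictly increasing")
        for n in self._cell_sizes().values():
            if n < 3:
                raise ConfigurationError("n_per_cell must be >= 3")

    def _cell_sizes(self) -> dict[tuple[str, float], int]:
        if isinstance(self.n_per_cell, int):
            return {(g, a): self.n_per_cell
                    for g in self.genotypes for a in self.ages}
        return {(g, a): int(self.n_per_cell[(g, a)])
                for g in self.genotypes for a in self.ages}


def _default_baselines() -> dict[str, tuple[float, float]]:
    # (mean, SD) for the wildtype 4-month reference condition. ERG in µV,
    # layers in µm, blot endpoints in TP-normalized arbitrary units.
    return {
        "rod_rmp3": (450.0, 55.0), "rod_vmax": (600.0, 70.0),
        "cone_rmp3": (120.0, 20.0), "cone_vmax": (150.0, 22.0),
        "pstr": (14.0, 3.5),
        "RNFL": (10.0, 1.2), "GCIPL": (70.0, 3.5), "INL": (25.0, 1.8),
        "OPL": (15.0, 1.8), "ONL": (60.0, 3.0),
        "th": (1.0, 0.20), "mouse_asyn": (1.0, 0.22),
        "human_asyn": (1.0, 0.30), "pser129_asyn": (0.8, 0.28),
    }


def _default_genotype_effects() -> dict[str, dict[float, float]]:
    # Additive HOM shifts in baseline-SD units per age: deficits concentrated
    # in the cone pathway and outer retina, earliest/largest in ONL and cone
    # P2; GCIPL slightly thicker; RNFL thinning only late; pSTR spared.
    return {
        "ONL": {4.0: -1.2, 6.0: -1.5, 14.0: -1.8},
        "OPL": {4.0: -0.6, 6.0: -0.8, 14.0: -1.0},
        "GCIPL": {4.0: 0.6, 6.0: 0.6, 14.0: 0.6},
        "RNFL": {14.0: -0.6},
        "cone_vmax": {4.0: -1.2, 6.0: -1.4, 14.0: -1.6},
        "cone_rmp3": {4.0: -1.0, 6.0: -1.2, 14.0: -1.5},
        "rod_rmp3": {4.0: -0.6, 6.0: -0.8, 14.0: -1.0},
        "rod_vmax": {4.0: -0.2, 6.0: -0.3, 14.0: -0.5},
        "th": {4.0: 1.0, 6.0: 1.0, 14.0: 1.0},
        "mouse_asyn": {4.0: 1.0, 6.0: 1.0, 14.0: 1.0},
    }


def _default_age_effects() -> dict[str, dict[float, float]]:
    # Shared (genotype-independent) ageing trends, SD units.
    return {
        "rod_rmp3": {6.0: -0.3, 14.0: -0.8},
        "rod_vmax": {6.0: -0.2, 14.0: -0.5},
        "cone_vmax": {6.0: -0.2, 14.0: -0.6},
    }


def _default_age_scale() -> dict[str, dict[float, float]]:
    # Multiplicative progression of the HOM-only transgene products.
    return {
        "human_asyn": {4.0: 1.0, 6.0: 1.3, 14.0: 1.8},
        "pser129_asyn": {4.0: 1.0, 6.0: 1.5, 14.0: 2.5},
    }


def _default_severity_coupling() -> dict[str, float]:
    # SD units per unit latent severity, HOM animals only.
    return {
        "ONL": -0.8, "cone_vmax": -0.8,
        "human_asyn": 0.8, "pser129_asyn": 0.8, "mouse_asyn": 0.3,
    }


@dataclass(frozen=True)
class EffectModel:
    baselines: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_baselines)
    genotype_effects: Mapping[str, Mapping[float, float]] = field(
        default_factory=_default_genotype_effects)
    age_effects: Mapping[str, Mapping[float, float]] = field(
        default_factory=_default_age_effects)
    age_scale: Mapping[str, Mapping[float, float]] = field(
        default_factory=_default_age_scale)
    severity_coupling: Mapping[str, float] = field(
        default_factory=_default_severity_coupling)

    def __post_init__(self) -> None:
        for table in (self.genotype_effects, self.age_effects,
                      self.age_scale, self.severity_coupling):
            for endpoint in table:
                if endpoint not in self.baselines:
                    raise ConfigurationError(
                        f"effect refers to unknown endpoint {endpoint!r}")
        for endpoint, (_, sd) in self.baselines.items():
            if sd <= 0:
                raise ConfigurationError(f"SD for {endpoint!r} must be > 0")

    def planted_mean(self, endpoint: str, genotype: str, age: float) -> float:
        """The exact group mean the simulator draws around."""
        mean, sd = self.baselines[endpoint]
        if endpoint in HOM_ONLY and genotype == WT:
            return 0.0
        scale = self.age_scale.get(endpoint, {}).get(age, 1.0)
        shift = self.age_effects.get(endpoint, {}).get(age, 0.0)
        if genotype == HOM:
            shift += self.genotype_effects.get(endpoint, {}).get(age, 0.0)
        return mean * scale + sd * shift

    def zeroed(self) -> "EffectModel":
        """Copy with every genotype effect and coupling removed (null model)."""
        return replace(self, genotype_effects={}, severity_coupling={},
                       age_scale={})


@dataclass(frozen=True)
class CohortDataset:
    data: pd.DataFrame          # one row per animal
    truth: pd.DataFrame         # planted means, (endpoint, genotype, age)
    design: StudyDesign
    effects: EffectModel
    seed: int


def simulate_cohort(design: StudyDesign, effects: EffectModel,
                    seed: int) -> CohortDataset:
    """Draw per-animal endpoints for the full design.

    WT values of HOM-only endpoints are exactly zero (no noise); all other
    endpoints are Gaussian around their planted mean with the latent-severity
    contribution added for HOM animals. Abundances are floored at zero.
    """
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for (genotype, age), n in design._cell_sizes().items():
        for j in range(n):
            severity = float(rng.standard_normal()) if genotype == HOM else 0.0
            row = {
                "animal_id": f"{genotype}{int(age)}m_{j:02d}",
                "genotype": genotype, "age": age,
                "sex": ("F", "M")[(idx + j) % 2] if design.sex_balance
                       else ("F", "M")[rng.integers(2)],
                "severity": severity,
            }
            for endpoint in ALL_ENDPOINTS:
                mean = effects.planted_mean(endpoint, genotype, age)
                if endpoint in HOM_ONLY and genotype == WT:
                    row[endpoint] = 0.0
                    continue
                _, sd = effects.baselines[endpoint]
                coupling = (effects.severity_coupling.get(endpoint, 0.0)
                            if genotype == HOM else 0.0)
                value = mean + sd * (coupling * severity + rng.standard_normal())
                if endpoint in BLOT_ENDPOINTS:
                    value = max(value, 0.0)
                row[endpoint] = value
            rows.append(row)
        idx += n
    data = pd.DataFrame(rows)
    data["TRT"] = data[list(LAYER_ENDPOINTS)].sum(axis=1)
    truth_rows = [
        {"endpoint": e, "genotype": g, "age": a,
         "planted_mean": effects.planted_mean(e, g, a)}
        for e in ALL_ENDPOINTS for g in design.genotypes for a in design.ages]
    return CohortDataset(data=data, truth=pd.DataFrame(truth_rows),
                         design=design, effects=effects, seed=int(seed))


# ---------------------------------------------------------------------------
# raw-input materialization
# ---------------------------------------------------------------------------

def waveforms_for_animal(row: Mapping[str, float],
                         tb: ergsim.Timebase = ergsim.Timebase(),
                         acc: ergsim.AccessoryParams | None = None,
                         seed: int | np.random.Generator = 0,
                         ) -> ergsim.WaveformFamily:
    """Emit a full flash family whose ground truth is the animal's endpoints."""
    if acc is None:
        # residual noise of an averaged sweep, not single-trace noise: peak
        # picking (pSTR, b-wave) is biased upward by wideband noise maxima
        acc = replace(ergsim.DEFAULT_ACCESSORY, noise_sd=3.0,
                      str_amplitude=max(float(row["pstr"]), 0.0))
    else:
        acc = replace(acc, str_amplitude=max(float(row["pstr"]), 0.0))
    rod_p3 = replace(ergsim.DEFAULT_ROD_P3, rm_p3=max(float(row["rod_rmp3"]), 0.0))
    rod_p2 = replace(ergsim.DEFAULT_ROD_P2, vmax=max(float(row["rod_vmax"]), 0.0))
    cone_p3 = replace(ergsim.DEFAULT_CONE_P3, rm_p3=max(float(row["cone_rmp3"]), 0.0))
    cone_p2 = replace(ergsim.DEFAULT_CONE_P2, vmax=max(float(row["cone_vmax"]), 0.0))
    return ergsim.generate_family(ergsim.default_protocol(), rod_p3, rod_p2,
                                  cone_p3, cone_p2, acc, tb, seed)


def grid_for_animal(row: Mapping[str, float], n: int = 96,
                    extent_mm: float = 4.05, pixel_noise_um: float = 1.5,
                    seed: int | np.random.Generator = 0) -> octthick.ThicknessGrid:
    """Emit an en-face thickness grid whose annulus means are the animal's
    planted layer endpoints (flat profiles plus pixel noise)."""
    rng = np.random.default_rng(seed)

    def profile(layer: str, r: np.ndarray) -> np.ndarray:
        base = float(row[layer]) * np.ones_like(r)
        return np.clip(base + rng.normal(0.0, pixel_noise_um, r.shape), 0.0, None)

    return octthick.radial_grid(profile, n=n, extent_mm=extent_mm)


def lane_table(cohort: CohortDataset) -> pd.DataFrame:
    """Per-lane densitometry table for the cohort.

    Band density is the endpoint value times the lane's total-protein load
    (so within-lane normalization exactly recovers the endpoint), with
    lane-to-lane TP load variation as real gels show.
    """
    rng = np.random.default_rng(cohort.seed + 104729)
    rows = []
    target_map = {"th": "TH", "mouse_asyn": "mouse_asyn",
                  "human_asyn": "human_asyn", "pser129_asyn": "pser129_asyn"}
    for _, animal in cohort.data.iterrows():
        for endpoint, target in target_map.items():
            tp = float(rng.uniform(800.0, 1200.0))
            rows.append({
                "animal_id": animal["animal_id"],
                "genotype": animal["genotype"], "age": animal["age"],
                "target": target,
                "band_density": float(animal[endpoint]) * tp,
                "total_protein": tp,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end study
# ---------------------------------------------------------------------------

#: Structure-function association panels: (x endpoint, y endpoint).
DEFAULT_CORRELATION_PAIRS = (
    ("OPL", "cone_rmp3"), ("ONL", "cone_rmp3"),
    ("OPL", "cone_vmax"), ("ONL", "cone_vmax"),
    ("all_asyn", "ONL"), ("pser129_asyn", "ONL"),
    ("all_asyn", "cone_vmax"), ("pser129_asyn", "cone_vmax"),
)


@dataclass(frozen=True)
class StudyConfig:
    from_raw: bool = False       # re-derive endpoints from waveforms/grids
    rout_q: float = 1.0          # percent
    grid_n: int = 96
    correlation_pairs: tuple[tuple[str, str], ...] = DEFAULT_CORRELATION_PAIRS
    reference_age: float = 4.0


def _reprocess_from_raw(cohort: CohortDataset, cfg: StudyConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    data = cohort.data.copy()
    dconf = ergdecomp.DecompositionConfig()
    for i, row in cohort.data.iterrows():
        family = waveforms_for_animal(row, seed=rng)
        try:
            dec = ergdecomp.decompose(family, dconf)
        except StageError:
            raise
        data.loc[i, "rod_rmp3"] = dec.rod_p3.params.rm_p3
        data.loc[i, "rod_vmax"] = dec.rod_p2.vmax
        data.loc[i, "cone_rmp3"] = dec.cone_p3.params.rm_p3
        data.loc[i, "cone_vmax"] = dec.cone_p2.vmax
        data.loc[i, "pstr"] = dec.pstr.amplitude
        grid = grid_for_animal(row, n=cfg.grid_n, seed=rng)
        summary = octthick.summarize_layers(grid)
        for layer in octthick.LAYERS:
            data.loc[i, layer] = summary.means[layer]
        data.loc[i, "TRT"] = summary.trt
    return data


def _screen_outliers(data: pd.DataFrame, endpoints: Sequence[str],
                     q: float) -> tuple[pd.DataFrame, dict[str, int]]:
    keep = pd.DataFrame(True, index=data.index, columns=list(endpoints))
    flagged = {}
    for endpoint in endpoints:
        count = 0
        for _, sub in data.groupby(["genotype", "age"], observed=True):
            screen = stats.rout_outliers(sub[endpoint].to_numpy(), q=q)
            keep.loc[sub.index[~screen.mask], endpoint] = False
            count += screen.n_flagged
        flagged[endpoint] = count
    return keep, flagged


def run_study(design: StudyDesign = StudyDesign(),
              effects: EffectModel = EffectModel(),
              config: StudyConfig = StudyConfig(),
              seed: int = 0) -> dict:
    """Simulate a cohort and run the full analysis pipeline on it.

    Stages: simulate → (optionally re-derive endpoints from raw waveforms
    and thickness grids) → per-group ROUT screening → genotype×age ANOVA
    with Sidak per-age contrasts → percent-relative summaries vs age-matched
    WT → densitometry percent-of-reference (with the HOM fallback for
    WT-null targets) and the composite 'ALL' α-SYN → Deming + Spearman
    association panels. Fully reproducible from ``seed``.
    """
    cohort = simulate_cohort(design, effects, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))
    if config.from_raw:
        data = _reprocess_from_raw(cohort, config, rng)
    else:
        data = cohort.data.copy()

    endpoints = list(ALL_ENDPOINTS) + ["TRT"]
    keep, flagged = _screen_outliers(data, endpoints, config.rout_q)

    anova, sidak, percent_rel = {}, {}, {}
    for endpoint in endpoints:
        sub = data[keep[endpoint]]
        if endpoint in HOM_ONLY:  # WT column is identically zero: no 2-way model
            continue
        anova[endpoint] = stats.two_way_anova(
            sub[endpoint], sub["genotype"], sub["age"])
        sidak[endpoint] = stats.sidak_comparisons(
            sub[endpoint], sub["genotype"], sub["age"])
        rel_rows = {}
        ref4 = sub[(sub["genotype"] == WT)
                   & (sub["age"] == config.reference_age)][endpoint]
        for age in design.ages:
            ref = sub[(sub["genotype"] == WT) & (sub["age"] == age)][endpoint]
            hom = sub[(sub["genotype"] == HOM) & (sub["age"] == age)][endpoint]
            summary = stats.percent_relative_summary(hom.to_numpy(),
                                                     ref.to_numpy())
            rel_rows[age] = {"hom_percent_mean": float(summary.percent.mean()),
                             "hom_percent_sem": summary.sem_percent}
        band = stats.percent_relative_summary(ref4.to_numpy(), ref4.to_numpy())
        percent_rel[endpoint] = {"per_age": rel_rows,
                                 "reference_ci": band.reference_ci}

    # densitometry percent-of-reference and the composite ALL α-SYN
    blot_percent = {}
    group = np.where((data["age"] == config.reference_age).to_numpy(),
                     data["genotype"].to_numpy(), "other")
    for endpoint in BLOT_ENDPOINTS:
        rel = blotquant.percent_of_reference(
            data[endpoint].to_numpy(), group,
            reference_group=WT, fallback_group=HOM)
        blot_percent[endpoint] = {
            "percent": np.array([r.percent_of_reference for r in rel]),
            "reference_group": rel[0].reference_group,
        }
    data = data.assign(all_asyn=[
        blotquant.total_alpha_syn(m, h, p) for m, h, p in zip(
            blot_percent["mouse_asyn"]["percent"],
            blot_percent["human_asyn"]["percent"],
            blot_percent["pser129_asyn"]["percent"])])

    correlations = {}
    for x_name, y_name in config.correlation_pairs:
        x = data[x_name].to_numpy()
        y = data[y_name].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        correlations[(x_name, y_name)] = {
            "deming": stats.deming_fit(x[ok], y[ok]),
            "spearman": stats.spearman(x[ok], y[ok]),
        }

    return {
        "seed": int(seed), "cohort": cohort, "data": data,
        "outliers_flagged": flagged, "anova": anova, "sidak": sidak,
        "percent_relative": percent_rel, "blot_percent": blot_percent,
        "correlations": correlations,
    }
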