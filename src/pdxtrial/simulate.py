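"""Synthetic PDX-cohort generator.

Produces cohorts with the statistical structure the downstream analyses
assume — so the whole pipeline is testable without any sequencing data:

* tumor-volume time series under the 1x1x1 design (one animal per model per
  arm), generated from a two-compartment growth law

      V(t) = V0 * [ f_r * exp(g t) + (1 - f_r) * exp(-k t) ]

  where a resistant fraction ``f_r`` of the tumor grows exponentially at rate
  ``g`` while the sensitive remainder regresses at kill rate ``k``. This is
  the minimal form producing the full CR/PR/SD/PD spectrum, including
  regression followed by regrowth. Untreated arms have k = 0, f_r = 1.
  Measurement noise is multiplicative lognormal on volume (caliper error
  scales with size), back-converted to a (length, width) pair with a fixed
  aspect ratio;
* feature x sample expression matrices (RNA and protein) with subtype block
  structure and per-sample spiked outlier features placed, by construction,
  well above Q3 + 1.5*IQR of their feature;
* mutation/CNA call tables with planted actionable alterations;
* clinical annotations including prior-drug counts and patient response
  calls. A model's expected resistant fraction increases linearly with its
  prior-drug count (slope ``prior_drug_effect``), the simplest monotone
  mechanism linking prior exposure to PDX chemoresistance.

Randomness uses one root seed; model ``i`` draws from
``SeedSequence(seed, spawn_key=(i,))`` (and ``(i, j)`` for its arm ``j``), so
existing models are unchanged when the cohort grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .response import VolumeSeries, classify_mrecist, response_record

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "latent_volume",
    "simulate_growth",
    "simulate_cohort",
    "write_cohort",
]

SUBTYPES = ("Basal", "HER2E", "LumB")
#: cohort composition the generator targets (roughly the development cohort)
SUBTYPE_PROBS = (0.70, 0.27, 0.03)

_PLANTED_ALTERATIONS = (
    # (gene, alteration, class, probability)
    ("PIK3CA", "H1047R", "hotspot-mutation", 0.15),
    ("ERBB2", "L755S", "hotspot-mutation", 0.04),
    ("FGFR1", "amp", "amplification", 0.10),
    ("MYC", "amp", "amplification", 0.15),
    ("CDH1", "Q23*", "truncating", 0.05),
    ("PTEN", "del", "deletion", 0.10),
)


class InvalidParameterError(ValueError):
    """A growth parameter violates its allowed range."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated PDX trial.

    Defaults mirror a ~30-model, four-drug, 28-day study with twice-weekly
    caliper measurements starting from 100 mm^3 tumors.
    """

    n_models: int = 30
    arms: tuple[str, ...] = (
        "untreated", "doxorubicin", "gemcitabine", "cisplatin", "paclitaxel",
    )
    measurement_days: tuple[float, ...] = (0, 4, 7, 11, 14, 18, 21, 25, 28)
    baseline_volume: float = 100.0
    growth_rate_range: tuple[float, float] = (0.02, 0.09)  # per day, untreated
    kill_rate_range: tuple[float, float] = (0.05, 0.45)  # per day, under drug
    resistant_fraction_range: tuple[float, float] = (0.0, 0.6)
    noise_cv: float = 0.05
    prior_drug_effect: float = 0.06  # resistant-fraction shift per prior drug
    max_prior_drugs: int = 9
    n_rna_features: int = 300
    n_rppa_features: int = 100
    n_outliers_per_sample: int = 2
    spike_magnitude: float = 3.0  # in IQR units above Q3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise InvalidParameterError("n_models must be >= 1")
        if "untreated" not in self.arms:
            raise InvalidParameterError("arms must include an untreated arm")
        days = tuple(float(d) for d in self.measurement_days)
        if days[0] != 0 or any(b <= a for a, b in zip(days, days[1:])):
            raise InvalidParameterError(
                "measurement_days must start at 0 and increase strictly"
            )
        if any(d < 0 for d in days):
            raise InvalidParameterError("measurement_days must be non-negative")
        for name in ("growth_rate_range", "kill_rate_range", "resistant_fraction_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InvalidParameterError(f"{name}: lower bound exceeds upper")
        lo, hi = self.resistant_fraction_range
        if lo < 0 or hi > 1:
            raise InvalidParameterError("resistant_fraction_range must lie in [0, 1]")
        if self.noise_cv < 0:
            raise InvalidParameterError("noise_cv must be >= 0")
        object.__setattr__(self, "measurement_days", days)
        object.__setattr__(self, "arms", tuple(self.arms))


@dataclass
class SimulatedCohort:
    """Everything a simulated trial produces, plus the generating truth."""

    measurements: pd.DataFrame  # model_id, arm, animal_id, day, length_mm, width_mm
    annotations: pd.DataFrame  # per-model clinical fields
    patient_responses: pd.DataFrame  # model_id, drug, response
    rna: "object"  # ExpressionMatrix
    rppa: "object"
    probe_map: dict[str, str]
    mutations: pd.DataFrame  # model_id, gene, alteration, class
    truth: pd.DataFrame  # per model x arm latent parameters + intended category
    spikes: pd.DataFrame  # planted expression outliers (platform, feature, sample)
    config: SimConfig = field(repr=False, default=None)


def latent_volume(
    t: np.ndarray | float,
    v0: float,
    growth_rate: float,
    kill_rate: float,
    resistant_fraction: float,
) -> np.ndarray | float:
    """Noiseless two-compartment volume at time ``t`` (days)."""
    t = np.asarray(t, dtype=float)
    f_r = resistant_fraction
    return v0 * (
        f_r * np.exp(growth_rate * t) + (1.0 - f_r) * np.exp(-kill_rate * t)
    )


def simulate_growth(
    v0: float,
    growth_rate: float,
    kill_rate: float,
    resistant_fraction: float,
    days,
    noise_cv: float = 0.0,
    seed: int | np.random.SeedSequence | None = None,
    aspect: float = 1.0,
    model_id: str = "model",
    arm: str = "arm",
    animal_id: str = "animal",
) -> tuple[VolumeSeries, pd.DataFrame]:
    """Simulate one animal's trajectory.

    Returns the measured :class:`VolumeSeries` and the corresponding caliper
    table rows (length = aspect x width, V = length x width^2 / 2). With
    ``noise_cv=0`` the measured volumes equal the latent model exactly.
    """
    days = np.asarray(list(days), dtype=float)
    if days[0] != 0 or np.any(np.diff(days) <= 0):
        raise InvalidParameterError("days must start at 0 and increase strictly")
    if not 0.0 <= resistant_fraction <= 1.0:
        raise InvalidParameterError("resistant_fraction must be in [0, 1]")
    if growth_rate < 0 or kill_rate < 0:
        raise InvalidParameterError("rates must be non-negative")
    if v0 <= 0:
        raise InvalidParameterError("baseline volume must be positive")
    latent = latent_volume(days, v0, growth_rate, kill_rate, resistant_fraction)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=days.size)
        measured = latent * noise
    else:
        measured = np.asarray(latent, dtype=float)
    width = np.cbrt(2.0 * measured / aspect)
    length = aspect * width
    series = VolumeSeries(
        model_id, arm, animal_id, tuple(days), tuple(measured)
    )
    calipers = pd.DataFrame(
        {
            "model_id": model_id,
            "arm": arm,
            "animal_id": animal_id,
            "day": days,
            "length_mm": length,
            "width_mm": width,
        }
    )
    return series, calipers


def _model_rng(seed: int, i: int, *rest: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, *rest)))


def _apply_spikes(
    mat: pd.DataFrame, spikes: list[dict], magnitude: float
) -> None:
    """Set each spiked cell to Q3 + magnitude*IQR of its own feature.

    Iterated so quartiles are the leave-value-in ones (including the spikes
    themselves): once the spiked cells sit above the Q3 rank position the
    position-based quantiles stop moving, so two passes reach the fixed point
    and every spike's outlier score equals ``magnitude`` exactly.
    """
    for _ in range(2):
        q1 = mat.quantile(0.25, axis=1)
        q3 = mat.quantile(0.75, axis=1)
        iqr = q3 - q1
        for s in spikes:
            f = s["feature"]
            mat.loc[f, s["sample"]] = q3[f] + magnitude * iqr[f]


def _expression_block(
    rng: np.random.Generator,
    prefix: str,
    n_features: int,
    models: list[str],
    subtype_of: dict[str, str],
    n_spikes: int,
    spike_magnitude: float,
) -> tuple[pd.DataFrame, list[dict]]:
    """Base N(0,1) matrix + subtype mean-shift blocks + planted spikes."""
    features = [f"{prefix}{i:04d}" for i in range(n_features)]
    mat = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n_features, len(models))),
        index=features,
        columns=models,
    )
    # subtype block structure: one feature block per subtype shifted up
    block = max(10, n_features // 10)
    for k, subtype in enumerate(SUBTYPES):
        rows = features[k * block : (k + 1) * block]
        cols = [m for m in models if subtype_of[m] == subtype]
        if cols:
            mat.loc[rows, cols] += 2.0
    spikes = []
    spikable = features[len(SUBTYPES) * block :]  # keep blocks clean
    for m in models:
        chosen = rng.choice(len(spikable), size=n_spikes, replace=False)
        for ci in chosen:
            spikes.append({"feature": spikable[ci], "sample": m})
    _apply_spikes(mat, spikes, spike_magnitude)
    return mat, spikes


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort under ``config``. Deterministic given seed."""
    from .expression import ExpressionMatrix

    models = [f"SIM{i:03d}X" for i in range(config.n_models)]
    drug_arms = [a for a in config.arms if a != "untreated"]

    meas_parts: list[pd.DataFrame] = []
    truth_rows: list[dict] = []
    anno_rows: list[dict] = []
    patient_rows: list[dict] = []
    mutation_rows: list[dict] = []

    for i, model in enumerate(models):
        rng = _model_rng(config.seed, i)
        g = rng.uniform(*config.growth_rate_range)
        # ~30% of patients are treatment-naive; the rest carry 1..max drugs
        if rng.random() < 0.3:
            prior = 0
        else:
            prior = int(rng.integers(1, config.max_prior_drugs + 1))
        # right-skewed within its range: naive tumors often lack resistant
        # clones, which is what produces complete responses in the trial
        lo, hi = config.resistant_fraction_range
        f_base = lo + (hi - lo) * rng.beta(0.7, 1.5)
        subtype = SUBTYPES[rng.choice(len(SUBTYPES), p=SUBTYPE_PROBS)]
        gbrca = "BRCA1" if rng.random() < 0.15 else ""
        anno_rows.append(
            {
                "model_id": model,
                "subtype": subtype,
                "er_status": "+" if subtype == "LumB" else "-",
                "her2_status": "+" if subtype == "HER2E" and rng.random() < 0.5 else "-",
                "gbrca": gbrca,
                "prior_drug_count": prior,
            }
        )
        for gene, alteration, klass, prob in _PLANTED_ALTERATIONS:
            if rng.random() < prob:
                mutation_rows.append(
                    {"model_id": model, "gene": gene,
                     "alteration": alteration, "class": klass}
                )
        for j, arm in enumerate(config.arms):
            if arm == "untreated":
                k, f_r = 0.0, 1.0
            else:
                k = rng.uniform(*config.kill_rate_range)
                f_r = float(
                    np.clip(f_base + config.prior_drug_effect * prior, 0.0, 1.0)
                )
            series, calipers = simulate_growth(
                config.baseline_volume, g, k, f_r,
                config.measurement_days, config.noise_cv,
                seed=np.random.SeedSequence(config.seed, spawn_key=(i, j)),
                model_id=model, arm=arm, animal_id=f"{model}-{arm}-1",
            )
            meas_parts.append(calipers)
            noiseless, _ = simulate_growth(
                config.baseline_volume, g, k, f_r,
                config.measurement_days, 0.0,
                model_id=model, arm=arm, animal_id="latent",
            )
            intended = response_record(noiseless).mrecist
            truth_rows.append(
                {
                    "model_id": model, "arm": arm, "growth_rate": g,
                    "kill_rate": k, "resistant_fraction": f_r,
                    "prior_drug_count": prior, "intended_mrecist": intended,
                }
            )
            if arm != "untreated":
                # retrospective patient call: matches the latent sensitivity
                # most of the time; some combinations were never given
                if rng.random() < 0.25:
                    response = "untested"
                else:
                    sensitive = intended in ("CR", "PR")
                    if rng.random() < 0.2:
                        sensitive = not sensitive
                    response = "sensitive" if sensitive else "resistant"
                patient_rows.append(
                    {"model_id": model, "drug": arm, "response": response}
                )

    subtype_of = {r["model_id"]: r["subtype"] for r in anno_rows}
    expr_rng = _model_rng(config.seed, config.n_models, 0)
    rna_vals, rna_spikes = _expression_block(
        expr_rng, "GENE", config.n_rna_features, models, subtype_of,
        config.n_outliers_per_sample, config.spike_magnitude,
    )
    rppa_rng = _model_rng(config.seed, config.n_models, 1)
    # protein probes track a transcript subset plus probe-level noise
    tracked = list(rna_vals.index[: config.n_rppa_features])
    probe_names = [f"P_{g}" for g in tracked]
    rppa_base = rna_vals.loc[tracked].to_numpy() * 0.8 + rppa_rng.normal(
        0.0, 0.6, size=(len(tracked), len(models))
    )
    rppa_vals = pd.DataFrame(rppa_base, index=probe_names, columns=models)
    rppa_spikes = []
    for m in models:
        ci = int(rppa_rng.integers(0, len(probe_names)))
        rppa_spikes.append({"feature": probe_names[ci], "sample": m})
    _apply_spikes(rppa_vals, rppa_spikes, config.spike_magnitude)

    spikes = pd.concat(
        [
            pd.DataFrame(rna_spikes).assign(platform="RNA"),
            pd.DataFrame(rppa_spikes).assign(platform="RPPA"),
        ],
        ignore_index=True,
    )[["platform", "feature", "sample"]]

    return SimulatedCohort(
        measurements=pd.concat(meas_parts, ignore_index=True),
        annotations=pd.DataFrame(anno_rows),
        patient_responses=pd.DataFrame(patient_rows),
        rna=ExpressionMatrix(rna_vals, platform="RNA", is_log2=True),
        rppa=ExpressionMatrix(rppa_vals, platform="RPPA", is_log2=True),
        probe_map=dict(zip(probe_names, tracked)),
        mutations=pd.DataFrame(
            mutation_rows, columns=["model_id", "gene", "alteration", "class"]
        ),
        truth=pd.DataFrame(truth_rows),
        spikes=spikes,
        config=config,
    )


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write all cohort tables to ``outdir``; returns the path of each file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": outdir / "measurements.csv",
        "annotations": outdir / "annotations.csv",
        "patient_responses": outdir / "patient_responses.csv",
        "mutations": outdir / "mutations.tsv",
        "rna": outdir / "rna.tsv",
        "rppa": outdir / "rppa.tsv",
        "truth": outdir / "truth.tsv",
    }
    cohort.measurements.to_csv(paths["measurements"], index=False)
    cohort.annotations.to_csv(paths["annotations"], index=False)
    cohort.patient_responses.to_csv(paths["patient_responses"], index=False)
    cohort.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    cohort.rna.values.to_csv(paths["rna"], sep="\t", index_label="feature")
    cohort.rppa.values.to_csv(paths["rppa"], sep="\t", index_label="feature")
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
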