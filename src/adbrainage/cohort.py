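"""Synthetic ADAD-like cohort generation.

Generates tabular cohorts that emulate the structure of a multi-site
autosomal dominant Alzheimer disease (ADAD) observational study: families
containing both mutation carriers (MC) and non-carrier relatives (NC),
estimated years to symptom onset (EYO), additive site and multiplicative
scanner batch effects on a brain-predicted age, a nonlinear carrier
divergence ramp with known onset, biomarker panels with group-specific
correlation targets, and seeded test-retest pairs.

Every downstream stage of the package (calibration, harmonization,
trajectory modelling, associations) is tested against the known ground
truth this module embeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSpec",
    "CohortSpecError",
    "GROUPS",
    "VARIANTS",
    "generate_cohort",
    "true_bag_curve",
    "generate_retest",
    "add_measure",
    "write_cohort_csv",
    "COLUMN_DICTIONARY",
]

GROUPS = ("NC", "asym_MC", "sym_MC")
VARIANTS = ("APP", "PSEN1<200", "PSEN1 200+", "PSEN2")

# Carrier-variant mix of the emulated study population.
_VARIANT_PROBS = (0.20, 0.28, 0.43, 0.09)

# Per-group demographic marginals (mean, sd) of the emulated cohort.
_EDU_PARAMS = {"NC": (15.0, 2.8), "asym_MC": (14.8, 2.7), "sym_MC": (13.7, 3.1)}
_MALE_PROB = {"NC": 0.44, "asym_MC": 0.43, "sym_MC": 0.50}
_APOE4_PROB = {"NC": 0.31, "asym_MC": 0.32, "sym_MC": 0.30}
_CDR_LEVELS = (0.5, 1.0, 2.0)
_CDR_PROBS = (0.595, 0.351, 0.054)
_EDU_CENTER = 14.7  # grand-mean education used to centre the education effect

# Plausible per-group biomarker scales: name -> group -> (mean, sd).
# Units: PiB PET SUVR; CSF ratios are dimensionless; plasma/CSF assay values
# in pg/mL; cognitive composite in z-units; CDR-SB in boxes.
BIOMARKER_SCALES = {
    "pib_suvr": {"NC": (1.10, 0.15), "asym_MC": (1.80, 0.70), "sym_MC": (2.80, 0.90)},
    "csf_ab42_40": {"NC": (0.095, 0.012), "asym_MC": (0.060, 0.020), "sym_MC": (0.040, 0.010)},
    "csf_ptau_ab40": {"NC": (0.005, 0.002), "asym_MC": (0.012, 0.006), "sym_MC": (0.022, 0.008)},
    "plasma_ptau181": {"NC": (1.5, 0.6), "asym_MC": (3.0, 1.5), "sym_MC": (6.0, 2.5)},
    "csf_nfl": {"NC": (600.0, 250.0), "asym_MC": (1200.0, 700.0), "sym_MC": (3000.0, 1500.0)},
    "plasma_nfl": {"NC": (8.0, 3.0), "asym_MC": (15.0, 8.0), "sym_MC": (35.0, 15.0)},
    "cognitive_composite": {"NC": (0.0, 0.7), "asym_MC": (-0.1, 0.8), "sym_MC": (-1.5, 1.0)},
    "cdr_sb": {"NC": (0.0, 0.0), "asym_MC": (0.05, 0.1), "sym_MC": (4.5, 3.0)},
}

# Default group-specific correlation targets (r_sym, r_asym) between each
# biomarker and the generator's true brain-age gap, matching the magnitudes
# the method is expected to recover.
DEFAULT_BIOMARKER_CORR_TARGETS = {
    "pib_suvr": (0.34, 0.24),
    "csf_ab42_40": (-0.14, -0.10),
    "csf_ptau_ab40": (0.45, 0.30),
    "plasma_ptau181": (0.53, 0.32),
    "csf_nfl": (0.46, 0.14),
    "plasma_nfl": (0.55, 0.17),
    "cognitive_composite": (-0.61, -0.25),
    "cdr_sb": (0.61, 0.0),
}

#: Versioned column dictionary for the cohort CSV (External interface).
COLUMN_DICTIONARY = {
    "version": 1,
    "columns": {
        "participant_id": "unique participant identifier",
        "family_id": "family identifier (families mix NC and MC members)",
        "site_id": "acquisition site identifier",
        "scanner_id": "scanner model identifier",
        "group": "NC | asym_MC | sym_MC",
        "variant": "APP | PSEN1<200 | PSEN1 200+ | PSEN2",
        "age": "chronological age, years",
        "eyo": "estimated years to symptom onset (age - onset age), years",
        "sex": "F | M",
        "education": "education, years",
        "apoe4": "APOE e4 carrier, 0/1",
        "cdr": "Clinical Dementia Rating global score",
        "raw_predicted_age": "uncorrected brain-predicted age, years",
        "cognitive_composite": "global cognitive composite, z-units",
        "cdr_sb": "CDR sum of boxes",
        "pib_suvr": "amyloid PET SUVR",
        "csf_ab42_40": "CSF Abeta42/40 ratio",
        "csf_ptau_ab40": "CSF pTau181/Abeta40 ratio",
        "plasma_ptau181": "plasma pTau-181, pg/mL",
        "csf_nfl": "CSF NfL, pg/mL",
        "plasma_nfl": "plasma NfL, pg/mL",
        "true_bag": "ground-truth brain-age gap, years (generator only)",
        "true_onset_age": "ground-truth onset age, years (generator only)",
        "true_family_intercept": "ground-truth family intercept, years (generator only)",
        "true_site_shift": "ground-truth additive site shift, years (generator only)",
    },
}

_BIOMARKER_COLS = list(BIOMARKER_SCALES)


class CohortSpecError(ValueError):
    """Invalid cohort specification; the message names the offending field."""


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults are the study conditions the generator emulates: group sizes
    and demographics of the emulated observational cohort, a carrier
    divergence ramp starting 7 years before expected onset reaching a mean
    elevation of 13.4 years at the symptomatic stage, a +3.15 year male
    offset and a -0.38 year-per-education-year slope, modest additive site
    and multiplicative scanner batch effects, and family clustering.
    """

    n_nc: int = 179
    n_asym_mc: int = 183
    n_sym_mc: int = 74
    age_params: dict = field(default_factory=lambda: {
        "NC": (37.5, 10.6), "asym_MC": (34.3, 9.1), "sym_MC": (46.3, 8.7)})
    eyo_params: dict = field(default_factory=lambda: {
        "NC": (-11.0, 11.4), "asym_MC": (-14.3, 9.0), "sym_MC": (1.4, 5.7)})
    n_sites: int = 15
    n_scanners: int = 9
    site_shift_sd: float = 1.5
    scanner_scale_sd: float = 0.1
    family_size_mean: float = 3.0
    family_sd: float = 2.0
    divergence_eyo: float = -7.0
    sym_elevation: float = 13.4
    noise_sd: float = 6.0
    sex_effect: float = 3.15
    education_slope: float = -0.38
    biomarker_corr_targets: dict = field(
        default_factory=lambda: dict(DEFAULT_BIOMARKER_CORR_TARGETS))
    biomarker_scales: dict | None = None   # overrides per-group (mean, sd)
    icc_target: float = 0.94
    prediction_slope: float = 1.0
    prediction_intercept: float = 0.0
    n_slices: int = 0
    slice_sd: float = 3.0
    seed: int = 20231219

    def validate(self) -> None:
        for name in ("n_nc", "n_asym_mc", "n_sym_mc", "n_sites", "n_scanners",
                     "n_slices"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise CohortSpecError(f"{name} must be a non-negative integer")
        for name in ("site_shift_sd", "scanner_scale_sd", "family_sd",
                     "noise_sd", "slice_sd"):
            if getattr(self, name) < 0:
                raise CohortSpecError(f"{name} must be >= 0")
        if self.family_size_mean < 1:
            raise CohortSpecError("family_size_mean must be >= 1")
        if not 0.0 <= self.icc_target <= 1.0:
            raise CohortSpecError("icc_target must be in [0, 1]")
        if self.divergence_eyo >= 0:
            raise CohortSpecError("divergence_eyo must be < 0 (pre-onset)")
        if self.prediction_slope == 0:
            raise CohortSpecError("prediction_slope must be nonzero")
        for name in ("age_params", "eyo_params"):
            params = getattr(self, name)
            for g in GROUPS:
                if g not in params:
                    raise CohortSpecError(f"{name} missing group {g!r}")
                mean, sd = params[g]
                if sd < 0:
                    raise CohortSpecError(f"{name}[{g!r}] sd must be >= 0")
        for biom, target in self.biomarker_corr_targets.items():
            r_sym, r_asym = target
            if not (-1 <= r_sym <= 1 and -1 <= r_asym <= 1):
                raise CohortSpecError(
                    f"biomarker_corr_targets[{biom!r}] must lie in [-1, 1]")

    def with_(self, **kwargs) -> "CohortSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def _ramp_scale(spec: CohortSpec) -> float:
    """Quadratic-ramp coefficient calibrated so the expected ramp height over
    the symptomatic-stage EYO distribution equals ``sym_elevation``.

    With EYO ~ N(mu, sd) in the symptomatic group and onset d, the second
    moment of the positive part is
    E[(E-d)_+^2] = (sd^2 + (mu-d)^2) * Phi(z) + sd*(mu-d) * phi(z),
    z = (mu-d)/sd.
    """
    mu, sd = spec.eyo_params["sym_MC"]
    d = spec.divergence_eyo
    if sd <= 0:
        m2 = max(mu - d, 0.0) ** 2
    else:
        z = (mu - d) / sd
        m2 = (sd**2 + (mu - d) ** 2) * stats.norm.cdf(z) \
            + sd * (mu - d) * stats.norm.pdf(z)
    if m2 <= 0:
        return 0.0
    return spec.sym_elevation / m2


def true_bag_curve(eyo, group: str, spec: CohortSpec):
    """Ground-truth mean brain-age-gap contribution of disease stage.

    Zero for non-carriers everywhere and for carriers before the divergence
    EYO; beyond it a smooth quadratic ramp, continuously differentiable at
    onset, calibrated so that its mean over the symptomatic-stage EYO
    distribution equals ``spec.sym_elevation``.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    eyo = np.asarray(eyo, dtype=float)
    if group == "NC":
        return np.zeros_like(eyo) if eyo.ndim else 0.0
    a = _ramp_scale(spec)
    out = a * np.square(np.clip(eyo - spec.divergence_eyo, 0.0, None))
    return out if eyo.ndim else float(out)


def _family_assignment(n: int, spec: CohortSpec, rng) -> np.ndarray:
    """Family index per participant; Poisson(+1) sizes, NC and MC mixed."""
    fams = []
    total = 0
    while total < n:
        size = 1 + rng.poisson(max(spec.family_size_mean - 1.0, 0.0))
        fams.append(size)
        total += size
    fam_idx = np.repeat(np.arange(len(fams)), fams)[:n]
    # shuffle participants over family slots so groups mix within families
    return fam_idx[rng.permutation(n)]


def _empty_table() -> pd.DataFrame:
    cols = list(COLUMN_DICTIONARY["columns"])
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in cols})
    for c in ("participant_id", "family_id", "site_id", "scanner_id",
              "group", "variant", "sex"):
        df[c] = df[c].astype(object)
    df["apoe4"] = df["apoe4"].astype(int)
    return df


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Generate one synthetic cohort table.

    Deterministic given ``spec`` and ``seed`` (``spec.seed`` if omitted).
    The uncorrected prediction is assembled as

        raw = intercept + slope * (age + true_bag + family + site_shift
                                   + scanner_scale * noise)

    where ``true_bag`` combines the carrier divergence ramp, the sex offset
    and the education slope.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    counts = {"NC": spec.n_nc, "asym_MC": spec.n_asym_mc, "sym_MC": spec.n_sym_mc}
    n = sum(counts.values())
    if n == 0:
        return _empty_table()

    group = np.repeat(list(counts), list(counts.values()))
    fam_idx = _family_assignment(n, spec, rng)
    n_fam = int(fam_idx.max()) + 1

    # family-level structure
    fam_variant = rng.choice(VARIANTS, size=n_fam, p=_VARIANT_PROBS)
    fam_intercept = rng.normal(0.0, spec.family_sd, size=n_fam)
    fam_site = rng.integers(spec.n_sites, size=n_fam)
    site_scanner = rng.integers(spec.n_scanners, size=spec.n_sites)
    site_shift = rng.normal(0.0, spec.site_shift_sd, size=spec.n_sites)
    scanner_scale = np.exp(rng.normal(0.0, spec.scanner_scale_sd,
                                      size=spec.n_scanners))

    age = np.empty(n)
    eyo = np.empty(n)
    edu = np.empty(n)
    male = np.empty(n, dtype=int)
    apoe4 = np.empty(n, dtype=int)
    for g in GROUPS:
        m = group == g
        k = int(m.sum())
        a_mu, a_sd = spec.age_params[g]
        e_mu, e_sd = spec.eyo_params[g]
        age[m] = rng.normal(a_mu, a_sd, size=k)
        eyo[m] = rng.normal(e_mu, e_sd, size=k)
        ed_mu, ed_sd = _EDU_PARAMS[g]
        edu[m] = np.clip(rng.normal(ed_mu, ed_sd, size=k), 6.0, 22.0)
        male[m] = rng.random(k) < _MALE_PROB[g]
        apoe4[m] = rng.random(k) < _APOE4_PROB[g]

    ramp = np.zeros(n)
    for g in ("asym_MC", "sym_MC"):
        m = group == g
        ramp[m] = true_bag_curve(eyo[m], g, spec)
    true_bag = ramp + spec.sex_effect * male \
        + spec.education_slope * (edu - _EDU_CENTER)

    site = fam_site[fam_idx]
    scanner = site_scanner[site]
    noise = rng.normal(0.0, spec.noise_sd, size=n) * scanner_scale[scanner]
    biology = age + true_bag + fam_intercept[fam_idx] + site_shift[site] + noise
    raw_pred = spec.prediction_intercept + spec.prediction_slope * biology

    cdr = np.zeros(n)
    m_sym = group == "sym_MC"
    cdr[m_sym] = rng.choice(_CDR_LEVELS, size=int(m_sym.sum()), p=_CDR_PROBS)

    df = pd.DataFrame({
        "participant_id": [f"P{i:04d}" for i in range(n)],
        "family_id": [f"F{j:03d}" for j in fam_idx],
        "site_id": [f"S{j:02d}" for j in site],
        "scanner_id": [f"SC{j:02d}" for j in scanner],
        "group": group,
        "variant": fam_variant[fam_idx],
        "age": age,
        "eyo": eyo,
        "sex": np.where(male == 1, "M", "F"),
        "education": edu,
        "apoe4": apoe4,
        "cdr": cdr,
        "raw_predicted_age": raw_pred,
    })

    # Biomarkers: within each group, mix the standardized measured biology
    # deviation (what remains in BAG after harmonization removes batch
    # effects) with fresh noise at the target correlation, then place on a
    # plausible scale. Targeting the measured signal reproduces the
    # intended biomarker-BAG correlation magnitudes.
    bio_dev = true_bag + fam_intercept[fam_idx] + noise
    scales = dict(BIOMARKER_SCALES)
    scales.update(spec.biomarker_scales or {})
    for biom in _BIOMARKER_COLS:
        vals = np.empty(n)
        r_sym, r_asym = spec.biomarker_corr_targets.get(biom, (0.0, 0.0))
        r_by_group = {"NC": 0.0, "asym_MC": r_asym, "sym_MC": r_sym}
        for g in GROUPS:
            m = group == g
            k = int(m.sum())
            mu, sd = scales[biom][g]
            r = r_by_group[g]
            eps = rng.normal(size=k)
            tb = bio_dev[m]
            if k > 1 and np.std(tb) > 0 and r != 0.0:
                z = (tb - tb.mean()) / tb.std()
                latent = r * z + np.sqrt(1.0 - r * r) * eps
            else:
                latent = eps
            vals[m] = mu + sd * latent
        if biom == "cdr_sb":
            vals = np.clip(vals, 0.0, None)
        elif biom != "cognitive_composite":
            floors = {g: 0.05 * scales[biom][g][0] for g in GROUPS}
            vals = np.maximum(vals, np.vectorize(floors.get)(group))
        df[biom] = vals

    df["true_bag"] = true_bag
    df["true_onset_age"] = age - eyo
    df["true_family_intercept"] = fam_intercept[fam_idx]
    df["true_site_shift"] = site_shift[site]

    if spec.n_slices > 0:
        # per-slice predictions jittered around a common centre; the
        # participant-level prediction is re-derived as their median so the
        # two representations stay consistent
        jitter = rng.normal(0.0, spec.slice_sd, size=(n, spec.n_slices))
        slices = raw_pred[:, None] + jitter
        for j in range(spec.n_slices):
            df[f"slice_{j:02d}"] = slices[:, j]
        df["raw_predicted_age"] = np.median(slices, axis=1)

    return df[list(COLUMN_DICTIONARY["columns"])
              + [c for c in df.columns if c.startswith("slice_")]]


def generate_retest(table: pd.DataFrame, icc_target: float,
                    interval_years: float = 2.11,
                    seed: int = 0,
                    column: str = "raw_predicted_age") -> pd.DataFrame:
    """Second-visit predictions with a target population ICC(A,1).

    Construction: with v1 the first-visit predictions (sample mean m, SD s),
    v2 = m + rho*(v1 - m) + sqrt(1-rho^2)*s*eta with eta ~ N(0,1). The pair
    is then exchangeable with equal variances, no systematic visit shift and
    population absolute-agreement ICC equal to rho. icc_target=1 returns an
    identical copy; icc_target=0 an independent one.
    """
    if not 0.0 <= icc_target <= 1.0:
        raise ValueError("icc_target must be in [0, 1]")
    rng = np.random.default_rng(seed)
    v1 = np.asarray(table[column], dtype=float)
    out = pd.DataFrame({"participant_id": table["participant_id"].to_numpy(),
                        "visit1": v1})
    if len(v1) == 0:
        out["visit2"] = np.array([], dtype=float)
        out["interval_years"] = np.array([], dtype=float)
        return out
    m = v1.mean()
    s = v1.std()
    eta = rng.normal(size=len(v1))
    rho = icc_target
    if rho == 1.0:
        v2 = v1.copy()
    else:
        v2 = m + rho * (v1 - m) + np.sqrt(1.0 - rho * rho) * s * eta
    out["visit2"] = v2
    out["interval_years"] = interval_years
    return out


def add_measure(table: pd.DataFrame, spec: CohortSpec, name: str,
                divergence_eyo: float, sym_elevation: float | None = None,
                noise_sd: float | None = None, seed: int = 0) -> pd.DataFrame:
    """Append an additional MRI-like measure with its own divergence truth.

    The new column shares the table's EYO, group, family and (rescaled)
    noise structure, enabling between-measure divergence comparisons with a
    known answer. Returns a new table; the input is not modified.
    """
    if divergence_eyo >= 0:
        raise ValueError("divergence_eyo must be < 0 (pre-onset)")
    sub = spec.with_(divergence_eyo=divergence_eyo,
                     sym_elevation=(spec.sym_elevation if sym_elevation is None
                                    else sym_elevation))
    rng = np.random.default_rng(seed)
    out = table.copy()
    eyo = out["eyo"].to_numpy(dtype=float)
    carrier = out["group"].to_numpy() != "NC"
    ramp = np.where(carrier, true_bag_curve(eyo, "asym_MC", sub), 0.0)
    fam = out["true_family_intercept"].to_numpy(dtype=float)
    sd = spec.noise_sd if noise_sd is None else noise_sd
    out[name] = ramp + fam + rng.normal(0.0, sd, size=len(out))
    return out


def write_cohort_csv(table: pd.DataFrame, path, blind: bool = False) -> None:
    """Write the cohort CSV; ``blind=True`` drops ground-truth columns."""
    df = table
    if blind:
        df = df[[c for c in df.columns if not c.startswith("true_")]]
    df.to_csv(path, index=False)
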