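"""Seeded synthetic cohorts and biopsy datasets with known ground truth.

The generators emulate the statistical structure the downstream analysis
assumes: a subjects × proteins relative-abundance matrix whose proteins fall
into latent-factor co-expression modules, motor outcomes driven by a small
set of causal proteins and measured four times per subject with realistic
visit-to-visit variability, and a muscle-biopsy log2 expression set with
diagnosis groups, ordinal histopathology grades, and planted effects.

Everything is deterministic given a seed: the same seed and parameters yield
byte-identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from serostab.preprocess import ProteinProfile

VISIT_LABELS = ("screening", "baseline", "week2", "week4")

#: Default module sizes: 11 modules, membership between 17 and 287, leaving a
#: small unassigned ("grey") remainder out of 1305 proteins.
DEFAULT_MODULE_SIZES = (287, 250, 180, 150, 120, 90, 70, 55, 40, 25, 17)

#: Visit-level coefficient of variation per outcome (fractions). Timed-test
#: velocities are the least reliable in young boys (~14-16%), walk distance
#: and NSAA the most reliable (~7-8%).
DEFAULT_VISIT_CV = {
    "TTSTAND_velocity": 0.16,
    "TTCLIMB_velocity": 0.14,
    "TTRW_velocity": 0.08,
    "6MWT": 0.07,
    "NSAA": 0.08,
}

#: Clinically plausible cohort-level location/scale for each outcome
#: (velocities in rise/s or m/s, 6MWT in meters, NSAA in points).
OUTCOME_SCALE = {
    "TTSTAND_velocity": (0.25, 0.06),
    "TTCLIMB_velocity": (0.50, 0.12),
    "TTRW_velocity": (1.70, 0.30),
    "6MWT": (380.0, 60.0),
    "NSAA": (22.0, 5.0),
}

#: Fraction of outcome variance explained by the causal-protein signal.
DEFAULT_SIGNAL_R2 = {
    "TTSTAND_velocity": 0.85,
    "TTCLIMB_velocity": 0.80,
    "TTRW_velocity": 0.55,
    "6MWT": 0.85,
    "NSAA": 0.70,
}


@dataclass
class SyntheticTruth:
    """Ground-truth record for a generated cohort.

    ``module_of`` maps each protein id to its planted module id (or
    ``"grey"``); ``loading`` gives the latent-factor loading in [0, 1];
    ``causal_set`` maps each outcome to its causal proteins with their
    coefficients on the standardized latent log-protein scale;
    ``outcome_noise_sd`` is the residual noise s.d. in outcome units;
    ``visit_cv`` the configured visit-level CV fraction per outcome.
    """

    module_of: dict[str, str]
    loading: dict[str, float]
    causal_set: dict[str, list[tuple[str, float]]]
    outcome_noise_sd: dict[str, float]
    visit_cv: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        for outcome, causal in self.causal_set.items():
            for pid, _ in causal:
                if pid not in self.module_of:
                    raise ValueError(
                        f"causal protein {pid!r} for {outcome!r} missing from module_of"
                    )
        for pid, lam in self.loading.items():
            if not (0.0 <= lam <= 1.0):
                raise ValueError(f"loading for {pid!r} outside [0, 1]: {lam}")
        for outcome, cv in self.visit_cv.items():
            if cv < 0:
                raise ValueError(f"visit_cv for {outcome!r} negative: {cv}")


@dataclass
class BiopsyTruth:
    """Planted effects for a synthetic biopsy expression set.

    ``de_genes`` holds log2 effects oriented as normal minus DMD (positive =
    higher in normal muscle); ``severity_genes`` holds per-grade log2 slopes
    on the mild(1)/moderate(2)/severe(3) scale (positive = increases with
    worsening histology); ``group_sizes`` is (n_normal, n_DMD, n_BMD).
    """

    de_genes: dict[str, float] = field(default_factory=dict)
    severity_genes: dict[str, float] = field(default_factory=dict)
    group_sizes: tuple[int, int, int] = (6, 17, 11)

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes):
            raise ValueError(f"group sizes must be positive: {self.group_sizes}")
        for name, eff in {**self.de_genes, **self.severity_genes}.items():
            if not np.isfinite(eff):
                raise ValueError(f"non-finite planted effect for {name!r}")


def _protein_ids(n: int) -> list[str]:
    return [f"APT{i:04d}" for i in range(1, n + 1)]


def default_cohort_spec() -> dict:
    """Default causal specification for :func:`generate_cohort`.

    Two modeled outcomes carry planted causal proteins: the strength outcome
    (TTSTAND velocity) driven by proteins from the two largest modules, and
    the endurance outcome (6MWT) driven by proteins from modules 2 and 3,
    sharing three causal proteins with the strength outcome. The two
    secondary timed tests reuse the strength signal (so cross-outcome
    transfer is meaningful) and NSAA blends both signals.
    """
    return {
        "causal_modules": {
            "TTSTAND_velocity": {"M01": 5, "M02": 3},
            "6MWT": {"M02": 3, "M03": 5},
        },
        "signal_of": {
            "TTCLIMB_velocity": "TTSTAND_velocity",
            "TTRW_velocity": "TTSTAND_velocity",
            "NSAA": "blend",
        },
        "module_sign": {"M01": 1.0, "M02": -1.0, "M03": 1.0},
        "signal_r2": dict(DEFAULT_SIGNAL_R2),
        "visit_cv": dict(DEFAULT_VISIT_CV),
        "causal_in_modules": True,
        "loading_range": (0.6, 0.9),
    }


def generate_cohort(
    n_subjects: int = 39,
    n_proteins: int = 1305,
    module_sizes: tuple[int, ...] | list[int] = DEFAULT_MODULE_SIZES,
    causal_spec: dict | None = None,
    seed: int = 0,
) -> tuple[ProteinProfile, pd.DataFrame, SyntheticTruth]:
    """Generate a synthetic serum-proteomics cohort with repeated outcomes.

    Protein ``i`` assigned to module ``m`` follows, on a latent log2 scale,
    ``x_i = lam_i * f_m + sqrt(1 - lam_i^2) * eps_i`` with ``f_m`` and
    ``eps_i`` standard normal per subject; unassigned ("grey") proteins are
    pure noise. Each outcome's true value is a linear combination of its
    causal proteins plus Gaussian noise, rescaled to a clinically plausible
    location/scale, and each of four visits observes ``y * (1 + cv * z)``.
    The exported abundance matrix is ``2**x * 1000`` (positive RFU scale;
    the pipeline consumes log-transformed values so the scale is immaterial).

    Returns ``(profile, outcome_series, truth)`` where ``outcome_series`` is
    a long-format DataFrame (subject_id, outcome, visit, value).
    """
    module_sizes = tuple(int(s) for s in module_sizes)
    if any(s <= 0 for s in module_sizes):
        raise ValueError("module sizes must be positive")
    if sum(module_sizes) > n_proteins:
        raise ValueError(
            f"module sizes sum to {sum(module_sizes)} > n_proteins={n_proteins}"
        )
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects")

    spec = default_cohort_spec()
    if causal_spec:
        spec.update(causal_spec)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pids = _protein_ids(n_proteins)
    module_ids = [f"M{k + 1:02d}" for k in range(len(module_sizes))]

    # Assign proteins to modules in blocks; remainder is grey.
    module_of: dict[str, str] = {}
    loading: dict[str, float] = {}
    lo, hi = spec["loading_range"]
    start = 0
    members: dict[str, list[str]] = {}
    for mid, size in zip(module_ids, module_sizes):
        block = pids[start : start + size]
        members[mid] = block
        lams = rng.uniform(lo, hi, size=size)
        for pid, lam in zip(block, lams):
            module_of[pid] = mid
            loading[pid] = float(lam)
        start += size
    grey = pids[start:]
    for pid in grey:
        module_of[pid] = "grey"
        loading[pid] = 0.0

    # Latent log-scale expression.
    factors = rng.standard_normal((n_subjects, len(module_ids)))
    noise = rng.standard_normal((n_subjects, n_proteins))
    x = np.empty((n_subjects, n_proteins))
    for j, pid in enumerate(pids):
        mid = module_of[pid]
        lam = loading[pid]
        if mid == "grey":
            x[:, j] = noise[:, j]
        else:
            m = module_ids.index(mid)
            x[:, j] = lam * factors[:, m] + np.sqrt(1.0 - lam * lam) * noise[:, j]

    # Causal proteins: highest-loading members of the designated modules
    # (or grey proteins when the out-of-module flag is set, to exercise the
    # screening step's blind spot).
    col_of = {pid: j for j, pid in enumerate(pids)}
    causal_set: dict[str, list[tuple[str, float]]] = {}
    used_grey = 0
    for outcome, module_counts in spec["causal_modules"].items():
        causal: list[tuple[str, float]] = []
        for mid, count in module_counts.items():
            if mid not in members and spec["causal_in_modules"]:
                raise ValueError(
                    f"causal module {mid!r} for outcome {outcome!r} does not exist "
                    f"(have {sorted(members)}); pass a matching causal_spec"
                )
            sign = spec["module_sign"].get(mid, 1.0)
            if spec["causal_in_modules"]:
                ranked = sorted(members[mid], key=lambda p: -loading[p])
                chosen = ranked[:count]
            else:
                chosen = grey[used_grey : used_grey + count]
                used_grey += count
            causal.extend((pid, sign * 1.0) for pid in chosen)
        causal_set[outcome] = causal

    # Outcome signals: primary outcomes from their causal sets; secondary
    # outcomes reuse a primary signal (with independent noise) or blend both.
    def signal_and_var(causal: list[tuple[str, float]]) -> tuple[np.ndarray, float]:
        sig = np.zeros(n_subjects)
        for pid, w in causal:
            sig += w * x[:, col_of[pid]]
        var = 0.0
        for pid_j, w_j in causal:
            for pid_k, w_k in causal:
                if pid_j == pid_k:
                    var += w_j * w_k
                elif module_of[pid_j] == module_of[pid_k] != "grey":
                    var += w_j * w_k * loading[pid_j] * loading[pid_k]
        return sig, var

    signals: dict[str, tuple[np.ndarray, float]] = {
        o: signal_and_var(c) for o, c in causal_set.items()
    }
    primary = list(causal_set)
    for outcome, source in spec["signal_of"].items():
        if source == "blend":
            sig = sum(signals[o][0] / np.sqrt(signals[o][1]) for o in primary)
            signals[outcome] = (sig, float(len(primary)))
            causal_set[outcome] = [
                (pid, w / np.sqrt(signals[o][1]))
                for o in primary
                for pid, w in causal_set[o]
            ]
        else:
            signals[outcome] = signals[source]
            causal_set[outcome] = list(causal_set[source])

    subjects = [f"S{i + 1:03d}" for i in range(n_subjects)]
    records: list[tuple[str, str, str, float]] = []
    outcome_noise_sd: dict[str, float] = {}
    visit_cv = dict(spec["visit_cv"])
    for outcome in OUTCOME_SCALE:
        mu, sd = OUTCOME_SCALE[outcome]
        r2 = spec["signal_r2"][outcome]
        sig, var_sig = signals[outcome]
        sigma = np.sqrt(var_sig * (1.0 - r2) / r2)
        z = (sig + sigma * rng.standard_normal(n_subjects)) / np.sqrt(
            var_sig + sigma * sigma
        )
        truth_val = np.clip(mu + sd * z, mu / 10.0, None)
        outcome_noise_sd[outcome] = float(sigma * sd / np.sqrt(var_sig + sigma * sigma))
        cv = visit_cv[outcome]
        for v in VISIT_LABELS:
            obs = truth_val * (1.0 + cv * rng.standard_normal(n_subjects))
            if outcome == "NSAA":
                obs = np.clip(np.round(obs), 0, 34)
            for s, val in zip(subjects, obs):
                records.append((s, outcome, v, float(val)))

    outcome_series = pd.DataFrame(
        records, columns=["subject_id", "outcome", "visit", "value"]
    )

    abundance = pd.DataFrame(
        1000.0 * np.exp2(x), index=subjects, columns=pids
    )
    annotations = pd.DataFrame(
        {
            "target_name": pids,
            "uniprot": [f"P{i:05d}" for i in range(1, n_proteins + 1)],
            "gene_symbol": [f"GENE{i:04d}" for i in range(1, n_proteins + 1)],
        },
        index=pids,
    )
    profile = ProteinProfile(abundance=abundance, annotations=annotations)

    truth = SyntheticTruth(
        module_of=module_of,
        loading=loading,
        causal_set=causal_set,
        outcome_noise_sd=outcome_noise_sd,
        visit_cv=visit_cv,
        seed=seed,
    )
    return profile, outcome_series, truth


def generate_selection_harness(
    seed: int,
    n_subjects: int = 39,
    n_candidates: int = 150,
    n_causal: int = 8,
    causal_loading: float = 0.387,
    background_loading: float = 0.5,
    signal_r2: float = 0.95,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Candidate-level benchmark for stability selection.

    Emulates the post-screening situation: ~150 correlated candidate
    proteins at the study's sample size, of which ``n_causal`` drive the
    outcome. The causal proteins form their own weakly coupled factor
    (pairwise r ≈ 0.15, so each retains identifiable conditional signal)
    with unit effects on the standardized latent scale; the remaining
    candidates sit in four background modules plus unstructured noise.
    ``signal_r2`` fixes the fraction of outcome variance explained by the
    causal combination; at the default the population marginal correlation
    of each causal protein with the outcome is ~0.5.

    Returns ``(X, y, causal_ids)`` with X column-standardized.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = n_subjects
    X = np.empty((n, n_candidates))
    lam = causal_loading
    f = rng.standard_normal(n)
    for j in range(n_causal):
        X[:, j] = lam * f + np.sqrt(1 - lam * lam) * rng.standard_normal(n)
    col = n_causal
    n_bg_modules = 4
    bg_size = (n_candidates - n_causal) // (n_bg_modules + 1)
    lb = background_loading
    for _ in range(n_bg_modules):
        g = rng.standard_normal(n)
        for _ in range(bg_size):
            X[:, col] = lb * g + np.sqrt(1 - lb * lb) * rng.standard_normal(n)
            col += 1
    while col < n_candidates:
        X[:, col] = rng.standard_normal(n)
        col += 1
    causal = list(range(n_causal))
    sig = X[:, causal].sum(axis=1)
    var_sig = n_causal + n_causal * (n_causal - 1) * lam * lam
    sigma = np.sqrt(var_sig * (1.0 - signal_r2) / signal_r2)
    y = sig + sigma * rng.standard_normal(n)
    cols = [f"c{j:03d}" for j in range(n_candidates)]
    Xdf = pd.DataFrame(X, columns=cols, index=[f"S{i:03d}" for i in range(n)])
    Xdf = (Xdf - Xdf.mean()) / Xdf.std(ddof=0)
    return Xdf, y, cols[:n_causal]


def default_biopsy_truth(
    genes: list[str], group_sizes: tuple[int, int, int] = (6, 17, 11)
) -> BiopsyTruth:
    """Plant biopsy effects for a gene panel at realistic magnitudes.

    Alternates direction across the panel; log2 normal-vs-DMD effects span
    roughly 1 to 2.6 (linear fold changes ~2 to ~6) and per-grade severity
    slopes span 0.4 to 0.8, matching the magnitudes seen for strong
    dystrophy markers (e.g. matrix/fibrosis genes). Signs are coupled so a
    gene up in DMD also rises with histological severity.
    """
    de: dict[str, float] = {}
    sev: dict[str, float] = {}
    for i, g in enumerate(sorted(genes)):
        sign = 1.0 if i % 2 == 0 else -1.0
        de[g] = sign * (1.0 + 1.6 * ((i * 7) % 5) / 4.0)
        # up in DMD (negative de) <=> up with severity (positive slope)
        sev[g] = -sign * (0.4 + 0.4 * ((i * 3) % 4) / 3.0)
    return BiopsyTruth(de_genes=de, severity_genes=sev, group_sizes=group_sizes)


@dataclass
class _BiopsyLayout:
    samples: list[str]
    diagnosis: list[str]
    grade: list[str]


def _biopsy_layout(group_sizes: tuple[int, int, int], rng) -> _BiopsyLayout:
    n_norm, n_dmd, n_bmd = group_sizes
    samples, diagnosis, grade = [], [], []
    grades = ("mild", "moderate", "severe")
    for i in range(n_norm):
        samples.append(f"NORM{i + 1:02d}")
        diagnosis.append("normal")
        grade.append("normal")
    for i in range(n_dmd):
        samples.append(f"DMD{i + 1:02d}")
        diagnosis.append("DMD")
        grade.append(grades[rng.integers(0, 3)])
    for i in range(n_bmd):
        samples.append(f"BMD{i + 1:02d}")
        diagnosis.append("BMD")
        grade.append(grades[rng.integers(0, 3)])
    return _BiopsyLayout(samples, diagnosis, grade)


GRADE_CODE = {"mild": 1, "moderate": 2, "severe": 3}


def generate_biopsy(
    truth: BiopsyTruth,
    n_probes_per_gene: dict[str, int] | int = 1,
    seed: int = 0,
    n_background: int = 300,
    gene_to_uniprot: dict[str, str] | None = None,
    noise_sd: float = 0.3,
    decoy_fraction: float = 0.2,
) -> tuple["BiopsyExpression", pd.DataFrame]:
    """Generate a synthetic biopsy log2 expression set with probe structure.

    Gene-level signal includes the planted normal-vs-DMD log2 effects and
    per-grade severity slopes from ``truth`` on top of a gene baseline.
    BMD samples sit halfway between normal and DMD for the diagnosis effect
    (milder disease) and follow their own histology grade for the severity
    effect. The probe table includes decoy probes with extension codes (not
    plain ``_at``) and attenuated secondary probes for multi-probe genes, to
    exercise the probe-filtering rules downstream.

    Returns ``(BiopsyExpression, probe_annotation)``; the probe annotation
    is also carried on the returned expression object.
    """
    from serostab.biopsy import BiopsyExpression

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    layout = _biopsy_layout(truth.group_sizes, rng)

    genes = sorted(set(truth.de_genes) | set(truth.severity_genes))
    genes += [f"BG{i:04d}" for i in range(1, n_background + 1)]
    if gene_to_uniprot is None:
        gene_to_uniprot = {}
    uniprot = {
        g: gene_to_uniprot.get(g, f"Q{i + 1:05d}") for i, g in enumerate(genes)
    }

    if isinstance(n_probes_per_gene, int):
        probes_per_gene = {g: n_probes_per_gene for g in genes}
    else:
        probes_per_gene = {g: n_probes_per_gene.get(g, 1) for g in genes}
    if any(n < 0 for n in probes_per_gene.values()):
        bad = {g: n for g, n in probes_per_gene.items() if n < 0}
        raise ValueError(f"negative probe counts: {bad}")

    n_samples = len(layout.samples)
    diag = np.asarray(layout.diagnosis)
    grade_num = np.array(
        [GRADE_CODE.get(g, 0) for g in layout.grade], dtype=float
    )
    is_normal = diag == "normal"
    is_bmd = diag == "BMD"

    rows, probe_rows = [], []
    stem = 1000
    for g in genes:
        base = float(rng.normal(7.0, 1.0))
        de = truth.de_genes.get(g, 0.0)
        slope = truth.severity_genes.get(g, 0.0)
        # DMD baseline is the reference: normal shifted by +de, BMD by +de/2.
        mean = np.full(n_samples, base)
        mean = mean + np.where(is_normal, de, np.where(is_bmd, 0.5 * de, 0.0))
        mean = mean + np.where(grade_num > 0, slope * (grade_num - 2.0), 0.0)
        for k in range(probes_per_gene[g]):
            stem += 1
            probe = f"{stem}_at"
            atten = 1.0 if k == 0 else 0.3
            vals = base + atten * (mean - base) + rng.normal(
                0.0, noise_sd, n_samples
            )
            rows.append((probe, vals))
            probe_rows.append((probe, uniprot[g], g))
        if rng.uniform() < decoy_fraction:
            stem += 1
            ext = "s" if rng.uniform() < 0.5 else "x"
            probe = f"{stem}_{ext}_at"
            rows.append((probe, base + rng.normal(0.0, noise_sd, n_samples)))
            probe_rows.append((probe, uniprot[g], g))

    expr = pd.DataFrame(
        {p: v for p, v in rows}, index=layout.samples
    ).T
    expr.index.name = "probe_id"
    meta = pd.DataFrame(
        {
            "sample_id": layout.samples,
            "diagnosis": layout.diagnosis,
            "grade": layout.grade,
        }
    ).set_index("sample_id")
    probe_annotation = pd.DataFrame(
        probe_rows, columns=["probe_id", "uniprot", "gene"]
    ).set_index("probe_id")

    bexpr = BiopsyExpression(
        expression=expr, metadata=meta, probe_annotation=probe_annotation
    )
    return bexpr, probe_annotation
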