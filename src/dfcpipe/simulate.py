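"""Synthetic resting-state cohort generator with transient connectivity effects.

Real resting-state fMRI cohorts for depression classification are rarely
deposited, so every downstream stage here is exercised on synthetic ROI time
series with a known ground truth.  The signal model is piecewise-stationary
Gaussian: innovations z_t ~ N(0, I_N) are mixed by the Cholesky factor of a
piecewise-constant target correlation matrix — the baseline structure for
controls, baseline plus a planted correlation delta on designated edges
during designated time epochs for patients — and then band-limited to the
configured frequency band (default 0.01–0.1 Hz at TR = 2 s) with a
zero-phase Butterworth filter.  Because the same linear filter is applied to
every region, the zero-lag correlation structure inside each stationary
epoch is preserved, so planted deltas are recoverable by windowed Pearson
correlation; epoch boundaries are smeared only over the filter's effective
memory.  A ``band_limit=False`` switch disables filtering for
exact-correlation unit tests.

Default cohort dimensions mirror a typical depression study: 43 patients vs
56 controls, T = 200 timepoints at TR = 2 s.  Group labels are +1 (patient)
and -1 (control).  Covariates (gender, education) are drawn from per-group
models so they are genuinely confounded with the diagnosis; clinical
severity scores (HAMD, HAMA) exist only for patients and may be linearly
coupled to a designated windowed-connectivity value plus noise, giving the
correlation analysis a recoverable planted coupling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal

from .connectivity import WindowScheme, enumerate_windows, windowed_connectivity

__all__ = [
    "EffectEdge",
    "GroupCovariates",
    "CovariateModel",
    "ClinicalCoupling",
    "CohortSpec",
    "SubjectRecord",
    "GroundTruth",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "default_atlas_table",
]


@dataclass(frozen=True)
class EffectEdge:
    """A planted group difference: patients' correlation on edge (i, j) is
    baseline + delta during timepoints [t_start, t_end)."""

    i: int
    j: int
    t_start: int
    t_end: int
    delta: float
    baseline: float = 0.0


@dataclass(frozen=True)
class GroupCovariates:
    male_rate: float
    education_mean: float
    education_sd: float


@dataclass(frozen=True)
class CovariateModel:
    """Per-group covariate distributions.

    Defaults echo a typical clinical cohort: controls more often male and
    more educated than patients, so gender and education are confounds that
    the screening stage must regress out.
    """

    patients: GroupCovariates = GroupCovariates(13 / 43, 11.44, 3.33)
    controls: GroupCovariates = GroupCovariates(30 / 56, 15.78, 4.33)


@dataclass(frozen=True)
class ClinicalCoupling:
    """score = intercept + coefficient * mean windowed correlation of
    ``edge`` over window indices [w_start, w_end] + N(0, noise_sd)."""

    scale: str  # "hamd" | "hama"
    edge: tuple[int, int]
    w_start: int
    w_end: int
    coefficient: float
    noise_sd: float
    intercept: float = 0.0


@dataclass
class CohortSpec:
    """Everything needed to generate one cohort deterministically."""

    n_patients: int = 43
    n_controls: int = 56
    n_regions: int = 30
    n_timepoints: int = 200
    tr_seconds: float = 2.0
    band: tuple[float, float] = (0.01, 0.1)
    effect_edges: list[EffectEdge] = field(default_factory=list)
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    clinical_model: list[ClinicalCoupling] = field(default_factory=list)
    clinical_means: dict[str, float] = field(
        default_factory=lambda: {"hamd": 23.35, "hama": 18.04}
    )
    clinical_sds: dict[str, float] = field(
        default_factory=lambda: {"hamd": 3.33, "hama": 3.33}
    )
    window_width: int = 50  # scheme used to realize clinical couplings
    window_step: int = 2
    band_limit: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        for e in self.effect_edges:
            if not (0 <= e.i < e.j < self.n_regions):
                raise ValueError(f"invalid edge ({e.i}, {e.j})")
            if not (0 <= e.t_start < e.t_end <= self.n_timepoints):
                raise ValueError(
                    f"epoch [{e.t_start}, {e.t_end}) outside [0, {self.n_timepoints}]"
                )
            if abs(e.baseline + e.delta) >= 1:
                raise ValueError(
                    f"|baseline + delta| must be < 1 on edge ({e.i}, {e.j})"
                )

    def window_scheme(self) -> WindowScheme:
        return WindowScheme(self.window_width, self.window_step, self.n_timepoints)


@dataclass
class SubjectRecord:
    subject_id: str
    timeseries: np.ndarray  # T x N
    group: int  # +1 patient, -1 control
    gender: int  # 1 male, 0 female
    education: float  # years
    hamd: float | None = None
    hama: float | None = None


@dataclass
class GroundTruth:
    """What was planted, in coordinates recoverable after windowing."""

    true_edges: list[dict]  # {"i","j","t_start","t_end","delta","windows":[...]}
    true_clinical_couplings: list[ClinicalCoupling]

    def feature_triples(self) -> set[tuple[int, int, int]]:
        """Planted (window, i, j) triples in FeatureIndex coordinates."""
        out: set[tuple[int, int, int]] = set()
        for e in self.true_edges:
            for w in e["windows"]:
                out.add((w, e["i"], e["j"]))
        return out


def _epoch_windows(scheme: WindowScheme, t_start: int, t_end: int) -> list[int]:
    """Windows fully contained in the epoch — where the planted delta is
    expressed at full strength."""
    return [
        w for w, (a, b) in enumerate(enumerate_windows(scheme))
        if a >= t_start and b <= t_end
    ]


def _segment_correlations(
    spec: CohortSpec, patient: bool
) -> list[tuple[int, int, np.ndarray]]:
    """Piecewise-constant target correlation: list of (t0, t1, C)."""
    n, T = spec.n_regions, spec.n_timepoints
    cuts = {0, T}
    if patient:
        for e in spec.effect_edges:
            cuts.update((e.t_start, e.t_end))
    cuts = sorted(cuts)
    segments = []
    for t0, t1 in zip(cuts[:-1], cuts[1:]):
        c = np.eye(n)
        for e in spec.effect_edges:
            rho = e.baseline
            if patient and e.t_start <= t0 and t1 <= e.t_end:
                rho = e.baseline + e.delta
            c[e.i, e.j] = c[e.j, e.i] = rho
        segments.append((t0, t1, c))
    return segments


def _cholesky_or_raise(c: np.ndarray, spec: CohortSpec, t0: int, t1: int) -> np.ndarray:
    try:
        return np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        edges = [
            (e.i, e.j) for e in spec.effect_edges
            if c[e.i, e.j] != 0.0
        ]
        raise ValueError(
            f"target correlation in epoch [{t0}, {t1}) is not positive definite; "
            f"offending edge set: {edges}"
        ) from None


def _bandpass(ts: np.ndarray, band: tuple[float, float], tr: float) -> np.ndarray:
    fs = 1.0 / tr
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, ts, axis=0)


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], GroundTruth]:
    """Generate one cohort.  Same spec + same seed => bit-identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    scheme = spec.window_scheme()

    # pre-factor the per-group segment covariances once
    factored = {}
    for patient in (True, False):
        segs = _segment_correlations(spec, patient)
        factored[patient] = [
            (t0, t1, _cholesky_or_raise(c, spec, t0, t1)) for t0, t1, c in segs
        ]

    subjects: list[SubjectRecord] = []
    groups = [+1] * spec.n_patients + [-1] * spec.n_controls
    for idx, group in enumerate(groups):
        patient = group == +1
        z = rng.standard_normal((spec.n_timepoints, spec.n_regions))
        ts = np.empty_like(z)
        for t0, t1, L in factored[patient]:
            ts[t0:t1] = z[t0:t1] @ L.T
        if spec.band_limit:
            ts = _bandpass(ts, spec.band, spec.tr_seconds)

        cov = spec.covariate_model.patients if patient else spec.covariate_model.controls
        gender = int(rng.random() < cov.male_rate)
        education = float(rng.normal(cov.education_mean, cov.education_sd))

        hamd = hama = None
        if patient:
            scores = {
                "hamd": float(rng.normal(spec.clinical_means["hamd"],
                                         spec.clinical_sds["hamd"])),
                "hama": float(rng.normal(spec.clinical_means["hama"],
                                         spec.clinical_sds["hama"])),
            }
            if spec.clinical_model:
                tensor = windowed_connectivity(ts, scheme)
                for cpl in spec.clinical_model:
                    val = float(
                        tensor.values[cpl.w_start : cpl.w_end + 1,
                                      cpl.edge[0], cpl.edge[1]].mean()
                    )
                    scores[cpl.scale] = (
                        cpl.intercept
                        + cpl.coefficient * val
                        + float(rng.normal(0.0, cpl.noise_sd))
                    )
            hamd, hama = scores["hamd"], scores["hama"]

        sid = f"sub-{idx + 1:03d}"
        subjects.append(
            SubjectRecord(sid, ts, group, gender, education, hamd, hama)
        )

    truth = GroundTruth(
        true_edges=[
            {
                "i": e.i, "j": e.j, "t_start": e.t_start, "t_end": e.t_end,
                "delta": e.delta,
                "windows": _epoch_windows(scheme, e.t_start, e.t_end),
            }
            for e in spec.effect_edges
        ],
        true_clinical_couplings=list(spec.clinical_model),
    )
    return subjects, truth


def default_atlas_table(
    n_regions: int, n_networks: int = 7
) -> "pd.DataFrame":  # noqa: F821
    """Synthetic atlas label table: region id, name, network assignment.

    Networks cycle through a 7-network taxonomy (VN, SMN, DAN, VAN, LN,
    FPN, DMN) purely as labels; no anatomical meaning is implied.
    """
    import pandas as pd

    networks = ["VN", "SMN", "DAN", "VAN", "LN", "FPN", "DMN"][:n_networks]
    return pd.DataFrame(
        {
            "region_id": np.arange(1, n_regions + 1),
            "region_name": [f"R{i:03d}" for i in range(1, n_regions + 1)],
            "network_name": [networks[i % len(networks)] for i in range(n_regions)],
        }
    )


def write_cohort(
    subjects: list[SubjectRecord],
    truth: GroundTruth,
    outdir: str | Path,
    atlas: "pd.DataFrame | None" = None,  # noqa: F821
) -> None:
    """Write one delimited time-series file per subject, a phenotype CSV,
    an atlas TSV, and the ground-truth JSON."""
    import pandas as pd

    outdir = Path(outdir)
    (outdir / "timeseries").mkdir(parents=True, exist_ok=True)
    n = subjects[0].timeseries.shape[1]
    header = "\t".join(str(i + 1) for i in range(n))
    for s in subjects:
        np.savetxt(
            outdir / "timeseries" / f"{s.subject_id}.tsv",
            s.timeseries, delimiter="\t", header=header, comments="",
        )
    pheno = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "group": [s.group for s in subjects],
            "gender": [s.gender for s in subjects],
            "education": [s.education for s in subjects],
            "hamd": [s.hamd for s in subjects],
            "hama": [s.hama for s in subjects],
        }
    )
    pheno.to_csv(outdir / "phenotype.csv", index=False)
    if atlas is None:
        atlas = default_atlas_table(n)
    atlas.to_csv(outdir / "atlas.tsv", sep="\t", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "true_edges": truth.true_edges,
                "true_clinical_couplings": [
                    asdict(c) for c in truth.true_clinical_couplings
                ],
            },
            fh, indent=1,
        )


def read_cohort(indir: str | Path) -> tuple[list[SubjectRecord], "pd.DataFrame"]:  # noqa: F821
    """Read a cohort written by :func:`write_cohort` (or any real export
    with the same layout).  Returns subjects and the atlas table."""
    import pandas as pd

    indir = Path(indir)
    pheno = pd.read_csv(indir / "phenotype.csv")
    subjects = []
    for row in pheno.itertuples(index=False):
        ts = np.loadtxt(indir / "timeseries" / f"{row.subject_id}.tsv",
                        delimiter="\t", skiprows=1)
        subjects.append(
            SubjectRecord(
                subject_id=row.subject_id,
                timeseries=ts,
                group=int(row.group),
                gender=int(row.gender),
                education=float(row.education),
                hamd=None if pd.isna(row.hamd) else float(row.hamd),
                hama=None if pd.isna(row.hama) else float(row.hama),
            )
        )
    atlas = pd.read_csv(indir / "atlas.tsv", sep="\t")
    return subjects, atlas
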