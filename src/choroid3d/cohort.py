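"""Synthetic per-eye biomarker cohorts with paired-eye structure.

Each eye contributes one row per sector (plus a ``mean`` row) with the four
choroidal biomarkers. Paired eyes (e.g. an affected eye and the fellow eye
of the same subject) share a subject-level random intercept scaled so that
the same-biomarker correlation between paired eyes equals
``within_subject_corr``. An optional cross-biomarker correlation matrix
induces latent coupling (e.g. thickness with vessel diameter) at both the
subject and the residual level, so the marginal cross-correlation matches
the requested value regardless of the pairing strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import seeded_rng

BIOMARKERS = ("mchvd_um", "ivd_um", "cth_um", "cvi_pct")
SECTORS_WITH_MEAN = ("mean", "nasal", "temporal", "inferior", "superior", "central")

# Group means and SDs per biomarker per sector used as generator defaults.
# Layout: biomarker -> sector -> group -> (mean, sd).
DEFAULT_GROUP_PARAMS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "cth_um": {
        "mean": {"cCSC": (288.90, 64.77), "fellow": (269.76, 71.17), "healthy": (223.97, 43.40)},
        "nasal": {"cCSC": (251.49, 62.73), "fellow": (237.42, 71.66), "healthy": (204.87, 62.18)},
        "temporal": {"cCSC": (276.94, 63.30), "fellow": (271.27, 77.97), "healthy": (232.52, 48.28)},
        "inferior": {"cCSC": (289.88, 77.33), "fellow": (244.83, 63.11), "healthy": (235.18, 39.29)},
        "superior": {"cCSC": (271.54, 71.68), "fellow": (267.13, 65.51), "healthy": (205.91, 45.49)},
        "central": {"cCSC": (364.62, 77.33), "fellow": (338.94, 91.12), "healthy": (251.03, 54.40)},
    },
    "cvi_pct": {
        "mean": {"cCSC": (38.14, 5.55), "fellow": (37.23, 6.41), "healthy": (40.65, 3.53)},
        "nasal": {"cCSC": (38.83, 3.64), "fellow": (37.33, 3.00), "healthy": (40.58, 5.35)},
        "temporal": {"cCSC": (39.31, 2.22), "fellow": (38.16, 2.98), "healthy": (40.35, 4.28)},
        "inferior": {"cCSC": (40.63, 3.50), "fellow": (40.25, 3.79), "healthy": (42.15, 3.54)},
        "superior": {"cCSC": (41.81, 2.30), "fellow": (41.27, 2.74), "healthy": (41.12, 3.63)},
        "central": {"cCSC": (39.53, 2.47), "fellow": (39.68, 2.39), "healthy": (40.64, 3.51)},
    },
    "mchvd_um": {
        "mean": {"cCSC": (362.50, 83.23), "fellow": (276.84, 26.89), "healthy": (233.28, 28.18)},
        "nasal": {"cCSC": (341.57, 84.19), "fellow": (263.32, 44.19), "healthy": (220.12, 35.68)},
        "temporal": {"cCSC": (365.82, 98.78), "fellow": (281.72, 43.39), "healthy": (239.93, 38.35)},
        "inferior": {"cCSC": (376.89, 91.04), "fellow": (289.85, 38.86), "healthy": (250.45, 41.12)},
        "superior": {"cCSC": (370.99, 289.94), "fellow": (289.14, 47.61), "healthy": (239.62, 43.83)},
        "central": {"cCSC": (357.26, 84.50), "fellow": (261.05, 43.30), "healthy": (224.93, 48.52)},
    },
    "ivd_um": {
        "mean": {"cCSC": (196.53, 23.58), "fellow": (225.05, 33.72), "healthy": (264.13, 46.06)},
        "nasal": {"cCSC": (189.70, 34.86), "fellow": (219.20, 42.89), "healthy": (255.60, 70.06)},
        "temporal": {"cCSC": (194.30, 44.57), "fellow": (235.37, 51.96), "healthy": (278.41, 59.44)},
        "inferior": {"cCSC": (192.96, 36.95), "fellow": (229.41, 60.82), "healthy": (238.76, 68.04)},
        "superior": {"cCSC": (202.66, 39.95), "fellow": (221.23, 58.98), "healthy": (259.31, 71.06)},
        "central": {"cCSC": (203.02, 41.90), "fellow": (200.04, 41.90), "healthy": (300.13, 76.68)},
    },
}

DEFAULT_GROUP_SIZES = {"cCSC": 30, "fellow": 22, "healthy": 26}


@dataclass
class GroupSpec:
    name: str
    n_eyes: int
    # biomarker -> sector -> (mean, sd)
    params: dict[str, dict[str, tuple[float, float]]]

    def validate(self) -> "GroupSpec":
        if self.n_eyes < 2:
            raise ValueError(f"group {self.name}: n_eyes must be >= 2")
        for bm, sectors in self.params.items():
            for sec, (mu, sd) in sectors.items():
                if sd < 0:
                    raise ValueError(f"group {self.name}, {bm}/{sec}: SD must be >= 0")
        return self


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    # (group_a, group_b, n_pairs): the first n_pairs eyes of each group share
    # a subject id (affected / fellow eye of the same patient).
    pairing: tuple[str, str, int] | None = None
    within_subject_corr: float = 0.5
    # optional 4x4 correlation matrix over BIOMARKERS (latent coupling)
    biomarker_corr: np.ndarray | None = None
    sectors: tuple[str, ...] = SECTORS_WITH_MEAN
    seed: int = 0

    def validate(self) -> "CohortSpec":
        if not 0.0 <= self.within_subject_corr <= 1.0:
            raise ValueError("within_subject_corr must lie in [0, 1]")
        names = [g.validate().name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("group names must be unique")
        if self.pairing is not None:
            ga, gb, n = self.pairing
            by_name = {g.name: g for g in self.groups}
            if ga not in by_name or gb not in by_name:
                raise ValueError(f"pairing references unknown group(s): {self.pairing}")
            if n > min(by_name[ga].n_eyes, by_name[gb].n_eyes):
                raise ValueError("pairing n_pairs exceeds a group size")
        if self.biomarker_corr is not None:
            c = np.asarray(self.biomarker_corr, dtype=float)
            if c.shape != (len(BIOMARKERS), len(BIOMARKERS)):
                raise ValueError("biomarker_corr must be 4x4 over BIOMARKERS")
            if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
                raise ValueError("biomarker_corr must be symmetric with unit diagonal")
        return self


def default_cohort_spec(seed: int = 0, within_subject_corr: float = 0.5,
                        group_sizes: dict[str, int] | None = None,
                        biomarker_corr: np.ndarray | None = None) -> CohortSpec:
    """CohortSpec matching the reference cohort structure (3 groups, 22 pairs)."""
    sizes = dict(DEFAULT_GROUP_SIZES)
    if group_sizes:
        sizes.update(group_sizes)
    groups = []
    for name, n in sizes.items():
        params = {bm: {sec: DEFAULT_GROUP_PARAMS[bm][sec][name]
                       for sec in SECTORS_WITH_MEAN}
                  for bm in BIOMARKERS}
        groups.append(GroupSpec(name=name, n_eyes=n, params=params))
    n_pairs = min(sizes.get("cCSC", 0), sizes.get("fellow", 0))
    pairing = ("cCSC", "fellow", n_pairs) if n_pairs else None
    return CohortSpec(groups=groups, pairing=pairing,
                      within_subject_corr=within_subject_corr,
                      biomarker_corr=biomarker_corr, seed=seed)


def _corr_chol(spec: CohortSpec) -> np.ndarray:
    if spec.biomarker_corr is None:
        return np.eye(len(BIOMARKERS))
    return np.linalg.cholesky(np.asarray(spec.biomarker_corr, dtype=float))


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per eye per sector with columns
    ``subject_id,eye,group,sector,mchvd_um,ivd_um,cth_um,cvi_pct``."""
    spec.validate()
    rng = seeded_rng(spec.seed, "cohort")
    chol = _corr_chol(spec)
    rho = spec.within_subject_corr
    n_bm = len(BIOMARKERS)

    # Assign subject ids; paired eyes share one.
    eye_rows: list[dict] = []  # group, subject_id, eye
    subject_counter = 0
    pair_subjects: dict[tuple[str, int], str] = {}
    if spec.pairing is not None:
        ga, gb, n_pairs = spec.pairing
        for i in range(n_pairs):
            sid = f"S{subject_counter:04d}"
            subject_counter += 1
            pair_subjects[(ga, i)] = sid
            pair_subjects[(gb, i)] = sid
    for g in spec.groups:
        for i in range(g.n_eyes):
            sid = pair_subjects.get((g.name, i))
            if sid is None:
                sid = f"S{subject_counter:04d}"
                subject_counter += 1
            eye_rows.append({"group": g.name, "subject_id": sid, "idx": i})

    # Latent subject effects: one correlated 4-vector per subject.
    subject_ids = sorted({r["subject_id"] for r in eye_rows})
    subject_latent = {sid: chol @ rng.standard_normal(n_bm) for sid in subject_ids}

    by_name = {g.name: g for g in spec.groups}
    records = []
    seen_subjects: set[str] = set()
    for row in eye_rows:
        g = by_name[row["group"]]
        b = subject_latent[row["subject_id"]]
        # OD/OS: paired eyes of a subject get opposite lateralities.
        eye = "OS" if row["subject_id"] in seen_subjects else "OD"
        seen_subjects.add(row["subject_id"])
        for sector in spec.sectors:
            eps = chol @ rng.standard_normal(n_bm)
            z = np.sqrt(rho) * b + np.sqrt(1.0 - rho) * eps
            rec = {"subject_id": row["subject_id"], "eye": eye,
                   "group": g.name, "sector": sector}
            for j, bm in enumerate(BIOMARKERS):
                mu, sd = g.params[bm][sector]
                rec[bm] = mu + sd * z[j]
            records.append(rec)

    cols = ["subject_id", "eye", "group", "sector", *BIOMARKERS]
    return pd.DataFrame.from_records(records)[cols]
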