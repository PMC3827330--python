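"""UK secondary-school grade point schemes and derived attainment scores.

Covers the scoring conventions used for medical-school cohort analyses:
best-three A-level points (pre-2010 tariff, maximum 30), GCSE/O-level mean,
total and count, per-group z-scoring of examination marks, and the
z-combination of O-level and GCSE means into a single variable for cohorts
that straddle the changeover between the two qualifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GradeScheme",
    "SubjectGrades",
    "ALEVEL_PRE2010",
    "GCSE_WITH_ASTAR",
    "GCSE_OLEVEL_1990",
    "best_three_alevel_points",
    "gcse_scores",
    "zscore",
    "combine_olevel_gcse",
    "read_subject_grades",
    "derive_scores",
]

GENERAL_STUDIES = "General Studies"


@dataclass(frozen=True)
class GradeScheme:
    """An ordered letter-to-points tariff for one qualification era."""

    name: str
    letter_to_points: dict[str, int]
    max_points_per_subject: int

    def __post_init__(self) -> None:
        pts = list(self.letter_to_points.values())
        if any(nxt >= prev for prev, nxt in zip(pts, pts[1:])):
            raise ValueError(f"scheme {self.name!r}: points must strictly decrease A(*)->F")
        if pts[0] != self.max_points_per_subject:
            raise ValueError(f"scheme {self.name!r}: top grade must score max_points_per_subject")

    def points(self, letter: str) -> int:
        try:
            return self.letter_to_points[letter]
        except KeyError:
            raise KeyError(
                f"unknown grade letter {letter!r} for scheme {self.name!r}; "
                f"known letters: {list(self.letter_to_points)}"
            ) from None


#: Pre-2010 A-level tariff: A=10, B=8, C=6, D=4, E=2, other=0.
ALEVEL_PRE2010 = GradeScheme(
    "alevel_pre2010", {"A": 10, "B": 8, "C": 6, "D": 4, "E": 2, "other": 0}, 10
)
#: GCSE tariff with A*: A*=6, A=5, B=4, C=3, D=2, E=1, F=0.
GCSE_WITH_ASTAR = GradeScheme(
    "gcse_with_astar", {"A*": 6, "A": 5, "B": 4, "C": 3, "D": 2, "E": 1, "F": 0}, 6
)
#: 1990-era GCSE / O-level tariff (no A*): A=5 ... F=0.
GCSE_OLEVEL_1990 = GradeScheme(
    "gcse_olevel_1990", {"A": 5, "B": 4, "C": 3, "D": 2, "E": 1, "F": 0}, 5
)

_EXAM_TYPES = ("A-level", "GCSE", "O-level")


@dataclass
class SubjectGrades:
    """Raw per-subject letter grades for one person and one exam type."""

    person_id: str
    exam_type: str
    grades: list[tuple[str, str]] = field(default_factory=list)  # (subject, letter)

    def __post_init__(self) -> None:
        if self.exam_type not in _EXAM_TYPES:
            raise ValueError(f"exam_type must be one of {_EXAM_TYPES}, got {self.exam_type!r}")
        subjects = [s for s, _ in self.grades]
        if len(subjects) != len(set(subjects)):
            dup = sorted({s for s in subjects if subjects.count(s) > 1})
            raise ValueError(f"duplicate subjects for person {self.person_id!r}: {dup}")


def best_three_alevel_points(
    grades: SubjectGrades,
    exclude_general_studies: bool = True,
    scheme: GradeScheme = ALEVEL_PRE2010,
) -> float:
    """Sum of the three highest A-level point values (max 30 pre-2010).

    General Studies is excluded by default, following the usual convention
    for medical-school selection.  Returns NaN when fewer than three
    gradeable subjects remain — a partial sum is never reported.
    """
    if grades.exam_type != "A-level":
        raise ValueError(f"expected A-level grades, got {grades.exam_type!r}")
    usable = [
        scheme.points(letter)
        for subject, letter in grades.grades
        if not (exclude_general_studies and subject == GENERAL_STUDIES)
    ]
    if len(usable) < 3:
        return float("nan")
    return float(sum(sorted(usable, reverse=True)[:3]))


def gcse_scores(
    grades: SubjectGrades, scheme: GradeScheme = GCSE_WITH_ASTAR
) -> tuple[float, float, float]:
    """(mean points, total points, count) over all listed subjects.

    An empty grade list yields a missing triple, not zeros: zero subjects is
    absence of information, not zero attainment.
    """
    if not grades.grades:
        return (float("nan"),) * 3
    pts = [scheme.points(letter) for _, letter in grades.grades]
    total = float(sum(pts))
    count = float(len(pts))
    return total / count, total, count


def zscore(values, groups=None) -> pd.Series:
    """Standardise to mean 0, sample SD 1, separately within each group.

    Used to put examination marks from different entry years on a common
    scale.  Missing values propagate; a group with zero spread or fewer
    than two non-missing values is an error naming the group.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    if groups is None:
        groups = pd.Series(np.zeros(len(s)))
    else:
        groups = pd.Series(np.asarray(groups)).reset_index(drop=True)
    out = pd.Series(np.full(len(s), np.nan))
    for g, idx in s.groupby(groups).groups.items():
        vals = s.loc[idx]
        ok = vals.dropna()
        if len(ok) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 non-missing values")
        sd = ok.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"group {g!r} has zero spread; cannot standardise")
        out.loc[idx] = (vals - ok.mean()) / sd
    return out


def combine_olevel_gcse(mean_gcse, mean_olevel) -> pd.Series:
    """Merge GCSE-only and O-level-only mean grades into one z-scored column.

    Each person must have at most one of the two means (mixed takers are
    excluded upstream).  Each column is z-scored over its own non-missing
    subset and the results coalesced, so the combined variable is on a
    common standardised scale regardless of which qualification was taken.
    """
    g = pd.Series(np.asarray(mean_gcse, dtype=float))
    o = pd.Series(np.asarray(mean_olevel, dtype=float))
    if len(g) != len(o):
        raise ValueError("columns must have equal length")
    both = (~g.isna()) & (~o.isna())
    if both.any():
        raise ValueError(
            f"{int(both.sum())} person(s) have both GCSE and O-level means; "
            "mixed takers must be excluded before combining"
        )
    out = pd.Series(np.full(len(g), np.nan))
    for col in (g, o):
        mask = ~col.isna()
        if mask.any():
            out[mask] = zscore(col[mask].to_numpy()).to_numpy()
    return out


# ---------------------------------------------------------------------------
# delimited-text I/O

def read_subject_grades(path_or_buffer) -> list[SubjectGrades]:
    """Read per-subject grades from CSV with columns
    person_id, exam_type, subject, grade."""
    df = pd.read_csv(path_or_buffer, dtype=str)
    required = {"person_id", "exam_type", "subject", "grade"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"grade file missing columns: {sorted(missing)}")
    out = []
    for (pid, etype), sub in df.groupby(["person_id", "exam_type"], sort=True):
        out.append(
            SubjectGrades(pid, etype, list(zip(sub["subject"], sub["grade"])))
        )
    return out


def derive_scores(
    records: list[SubjectGrades],
    gcse_scheme: GradeScheme = GCSE_WITH_ASTAR,
) -> pd.DataFrame:
    """Best-three A-level and GCSE summary scores per person.

    Returns a frame indexed by person_id with columns ``best3_alevel``,
    ``mean_gcse``, ``total_gcse``, ``n_gcse``.
    """
    rows: dict[str, dict] = {}
    for rec in records:
        row = rows.setdefault(rec.person_id, {})
        if rec.exam_type == "A-level":
            row["best3_alevel"] = best_three_alevel_points(rec)
        elif rec.exam_type in ("GCSE", "O-level"):
            mean, total, count = gcse_scores(rec, gcse_scheme)
            row["mean_gcse"], row["total_gcse"], row["n_gcse"] = mean, total, count
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "person_id"
    for col in ("best3_alevel", "mean_gcse", "total_gcse", "n_gcse"):
        if col not in df.columns:
            df[col] = np.nan
    return df[["best3_alevel", "mean_gcse", "total_gcse", "n_gcse"]]
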