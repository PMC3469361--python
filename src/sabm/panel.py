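"""Two-wave school network panels: data model, I/O and sample construction.

A :class:`SchoolPanel` holds one school's directed friendship network at two
observation waves, an ordinal alcohol-use frequency per actor (six survey
categories, coded 1..6), actor covariates, and wave-2 response indicators.
Sample-construction rules operate on panels: isolate removal, last
observation carry forward (LOCF) imputation for wave-2 non-responders, and
the Jaccard-stability screen used to decide whether a school is stable
enough for actor-based model estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

BEHAVIOR_MIN = 1
BEHAVIOR_MAX = 6

#: Covariate columns the analysis knows about, with the dtype they are cast to.
KNOWN_COVARIATES = {
    "age": float,
    "male": int,
    "minority": int,
    "race": str,
    "parent_drinking": int,
    "family_bonding": int,
}

DEFAULT_SCHEMA = {
    "source": "source",
    "target": "target",
    "actor_id": "actor_id",
    "behavior_wave1": "alcohol_w1",
    "behavior_wave2": "alcohol_w2",
    "responded_wave2": "responded_w2",
    "age": "age",
    "male": "male",
    "minority": "minority",
    "race": "race",
    "parent_drinking": "parent_drinking",
    "family_bonding": "family_bonding",
}


class PanelError(ValueError):
    """Invalid or inconsistent panel input."""


class DegenerateSchoolError(PanelError):
    """A school too small or too empty to analyze."""


class UndefinedIndexError(PanelError):
    """Jaccard index undefined: no ties at either wave."""


@dataclass
class SchoolPanel:
    """One school's two-wave directed network + behavior + covariates.

    Tie relations are dense 0/1 arrays of shape ``(n, n)`` with an empty
    diagonal; ``wave1[i, j] == 1`` means actor *i* nominated *j* at wave 1.
    Behavior is the 6-category alcohol-use frequency. ``imputed_tie_mask``
    flags wave-2 cells filled by carry-forward; it can only be set on rows of
    non-responders, whose outgoing nominations are unobserved at wave 2.
    """

    school_id: str
    actor_ids: list[str]
    wave1: np.ndarray
    wave2: np.ndarray
    behavior1: np.ndarray
    behavior2: np.ndarray
    covariates: pd.DataFrame
    responded_wave2: np.ndarray
    imputed_tie_mask: np.ndarray = None  # type: ignore[assignment]
    behavior2_imputed: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.actor_ids)
        self.wave1 = np.asarray(self.wave1, dtype=np.int8)
        self.wave2 = np.asarray(self.wave2, dtype=np.int8)
        self.behavior1 = np.asarray(self.behavior1, dtype=np.int64)
        self.behavior2 = np.asarray(self.behavior2, dtype=np.int64)
        self.responded_wave2 = np.asarray(self.responded_wave2, dtype=bool)
        if self.imputed_tie_mask is None:
            self.imputed_tie_mask = np.zeros((n, n), dtype=bool)
        if self.behavior2_imputed is None:
            self.behavior2_imputed = np.zeros(n, dtype=bool)
        self.imputed_tie_mask = np.asarray(self.imputed_tie_mask, dtype=bool)
        self.behavior2_imputed = np.asarray(self.behavior2_imputed, dtype=bool)
        self.validate()

    @property
    def n_actors(self) -> int:
        return len(self.actor_ids)

    def validate(self) -> None:
        n = self.n_actors
        if len(set(self.actor_ids)) != n:
            raise PanelError(f"duplicate actor identifiers in school {self.school_id!r}")
        for name, x in (("wave1", self.wave1), ("wave2", self.wave2)):
            if x.shape != (n, n):
                raise PanelError(f"{name} has shape {x.shape}, expected {(n, n)}")
            if np.any(np.diag(x) != 0):
                raise PanelError(f"{name} has self-ties")
            if not np.isin(x, (0, 1)).all():
                raise PanelError(f"{name} must be binary")
        for name, z in (("behavior1", self.behavior1), ("behavior2", self.behavior2)):
            if z.shape != (n,):
                raise PanelError(f"{name} has shape {z.shape}, expected ({n},)")
            if z.min(initial=BEHAVIOR_MIN) < BEHAVIOR_MIN or z.max(initial=BEHAVIOR_MAX) > BEHAVIOR_MAX:
                bad = z[(z < BEHAVIOR_MIN) | (z > BEHAVIOR_MAX)]
                raise PanelError(
                    f"{name} outside {BEHAVIOR_MIN}..{BEHAVIOR_MAX}: {bad[:5].tolist()}"
                )
        if len(self.covariates) != n or list(self.covariates.index) != list(self.actor_ids):
            raise PanelError("covariate table must be indexed by actor_ids in order")
        if self.imputed_tie_mask.any():
            bad_rows = self.imputed_tie_mask.any(axis=1) & self.responded_wave2
            if bad_rows.any():
                raise PanelError("imputed_tie_mask set on rows of wave-2 responders")

    def copy(self) -> "SchoolPanel":
        return replace(
            self,
            actor_ids=list(self.actor_ids),
            wave1=self.wave1.copy(),
            wave2=self.wave2.copy(),
            behavior1=self.behavior1.copy(),
            behavior2=self.behavior2.copy(),
            covariates=self.covariates.copy(),
            responded_wave2=self.responded_wave2.copy(),
            imputed_tie_mask=self.imputed_tie_mask.copy(),
            behavior2_imputed=self.behavior2_imputed.copy(),
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class JaccardCounts:
    """Tie-turnover counts between waves: stable / formed / dissolved."""

    f11: int
    f01: int
    f10: int

    def __post_init__(self) -> None:
        if min(self.f11, self.f01, self.f10) < 0:
            raise PanelError("Jaccard counts must be non-negative")


def jaccard_index(counts: JaccardCounts) -> float:
    """Stability index J = F11 / (F11 + F01 + F10) in [0, 1].

    F11 counts ties present at both waves, F01 ties newly formed at wave 2,
    F10 ties dissolved after wave 1.
    """
    total = counts.f11 + counts.f01 + counts.f10
    if total == 0:
        raise UndefinedIndexError("no ties at either wave: Jaccard index undefined")
    return counts.f11 / total


def jaccard_counts(panel: SchoolPanel) -> JaccardCounts:
    """Turnover counts over *observed* cells only.

    Rows of wave-2 non-responders are excluded: their wave-2 entries are
    either missing or carry-forward copies of wave 1, and counting copies
    would inflate apparent stability.
    """
    obs = panel.responded_wave2
    w1 = panel.wave1[obs]
    w2 = panel.wave2[obs]
    f11 = int(((w1 == 1) & (w2 == 1)).sum())
    f01 = int(((w1 == 0) & (w2 == 1)).sum())
    f10 = int(((w1 == 1) & (w2 == 0)).sum())
    return JaccardCounts(f11, f01, f10)


def screen_school(panel: SchoolPanel, threshold: float = 0.20) -> bool:
    """Retain a school iff its Jaccard stability is at or above ``threshold``.

    Low between-wave stability casts doubt on the reliability of the reported
    friendship data and risks non-convergence of the iterative estimation;
    0.20 is the conventional floor.  Boundary inclusive: J == threshold
    retains.
    """
    return jaccard_index(jaccard_counts(panel)) >= threshold


def filter_isolates(panel: SchoolPanel) -> SchoolPanel:
    """Drop actors with no incoming and no outgoing tie at either wave.

    The analysis sample keeps only subjects who named or were named by at
    least one friend at wave 1 or wave 2.  Idempotent: a retained actor has a
    tie to another retained actor or to a dropped isolate — but dropped
    isolates have no ties at all, so all retained ties survive re-indexing.
    """
    deg = (
        panel.wave1.sum(axis=0) + panel.wave1.sum(axis=1)
        + panel.wave2.sum(axis=0) + panel.wave2.sum(axis=1)
    )
    keep = np.flatnonzero(deg > 0)
    if keep.size < 2:
        raise DegenerateSchoolError(
            f"school {panel.school_id!r}: fewer than 2 non-isolated actors remain"
        )
    if keep.size == panel.n_actors:
        return panel.copy()
    ids = [panel.actor_ids[i] for i in keep]
    return replace(
        panel,
        actor_ids=ids,
        wave1=panel.wave1[np.ix_(keep, keep)],
        wave2=panel.wave2[np.ix_(keep, keep)],
        behavior1=panel.behavior1[keep],
        behavior2=panel.behavior2[keep],
        covariates=panel.covariates.iloc[keep],
        responded_wave2=panel.responded_wave2[keep],
        imputed_tie_mask=panel.imputed_tie_mask[np.ix_(keep, keep)],
        behavior2_imputed=panel.behavior2_imputed[keep],
    )


def impute_locf(panel: SchoolPanel) -> SchoolPanel:
    """Carry wave-1 data forward for wave-2 non-responders, flagged.

    Outgoing tie rows of non-responders are copied from wave 1 and marked
    non-informative in ``imputed_tie_mask``; their behavior is carried
    forward and flagged.  Incoming ties to non-responders, reported by
    responders, are left exactly as reported and keep contributing to
    estimation.
    """
    out = panel.copy()
    nonresp = ~out.responded_wave2
    if nonresp.any():
        out.wave2[nonresp, :] = out.wave1[nonresp, :]
        out.imputed_tie_mask[nonresp, :] = True
        np.fill_diagonal(out.imputed_tie_mask, False)
        out.behavior2[nonresp] = out.behavior1[nonresp]
        out.behavior2_imputed[nonresp] = True
    return out


def retention_percent(n1: int, n2: int) -> float:
    """Retention as a percentage, floored at one decimal (89.69...% -> 89.6)."""
    if n1 <= 0:
        raise PanelError("wave-1 count must be positive")
    return math.floor(1000 * n2 / n1) / 10


@dataclass
class AttritionSummary:
    n_wave1: int
    n_wave2: int
    retention_pct: float
    behavior_by_response: pd.DataFrame | None = None


def attrition_summary(panel_or_study) -> AttritionSummary:
    """Wave-1/2 counts, floored retention percent, and the wave-1 alcohol
    distribution split by wave-2 response status.

    Accepts a single panel, an iterable of panels, or a bare ``(n1, n2)``
    count pair (in which case no behavior table is produced).
    """
    if isinstance(panel_or_study, tuple) and len(panel_or_study) == 2:
        n1, n2 = panel_or_study
        return AttritionSummary(int(n1), int(n2), retention_percent(int(n1), int(n2)))
    panels = (
        [panel_or_study] if isinstance(panel_or_study, SchoolPanel) else list(panel_or_study)
    )
    z1 = np.concatenate([p.behavior1 for p in panels])
    resp = np.concatenate([p.responded_wave2 for p in panels])
    n1 = z1.size
    n2 = int(resp.sum())
    levels = np.arange(BEHAVIOR_MIN, BEHAVIOR_MAX + 1)
    table = pd.DataFrame(
        {
            "responders": [np.mean(z1[resp] == k) if n2 else np.nan for k in levels],
            "non_responders": [
                np.mean(z1[~resp] == k) if n1 - n2 else np.nan for k in levels
            ],
        },
        index=pd.Index(levels, name="alcohol_wave1"),
    )
    return AttritionSummary(n1, n2, retention_percent(n1, n2), table)


# ---------------------------------------------------------------------------
# I/O


def _read_edges(path, schema: dict) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    for role in ("source", "target"):
        col = schema[role]
        if col not in df.columns:
            raise PanelError(f"edge file {path}: missing column {col!r}")
    return df[[schema["source"], schema["target"]]].rename(
        columns={schema["source"]: "source", schema["target"]: "target"}
    )


def read_panel(
    edge_list_paths,
    covariate_path,
    schema: dict | None = None,
    school_id: str = "school",
) -> SchoolPanel:
    """Read one school from two edge-list files and a covariate table.

    ``edge_list_paths`` is a ``(wave1_path, wave2_path)`` pair of delimited
    text files with source/target identifier columns; the covariate file has
    one row per actor keyed on the same identifiers and carries the behavior
    columns and (optionally) the wave-2 response flag.  Actors present in the
    covariate file but in no edge file are retained as isolates (removed
    later by :func:`filter_isolates`).  Duplicate edge rows collapse to a
    single tie.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    cov = pd.read_csv(covariate_path, sep=None, engine="python")
    idcol = schema["actor_id"]
    if idcol not in cov.columns:
        raise PanelError(f"covariate file: missing identifier column {idcol!r}")
    ids = cov[idcol].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise PanelError("covariate file: duplicate actor identifiers")
    index = {a: i for i, a in enumerate(ids)}
    n = len(ids)

    mats = []
    for wave, path in zip((1, 2), edge_list_paths):
        x = np.zeros((n, n), dtype=np.int8)
        edges = _read_edges(path, schema)
        for row in edges.itertuples(index=False):
            s, t = str(row.source), str(row.target)
            for a in (s, t):
                if a not in index:
                    raise PanelError(
                        f"wave-{wave} edge file: unknown actor {a!r} in row ({s}, {t})"
                    )
            if s != t:
                x[index[s], index[t]] = 1
        mats.append(x)

    def _behavior(col_role: str) -> np.ndarray:
        col = schema[col_role]
        if col not in cov.columns:
            raise PanelError(f"covariate file: missing behavior column {col!r}")
        z = cov[col].to_numpy()
        zi = np.asarray(z, dtype=float)
        if np.any((zi < BEHAVIOR_MIN) | (zi > BEHAVIOR_MAX) | (zi != np.round(zi))):
            raise PanelError(
                f"behavior column {col!r} has values outside {BEHAVIOR_MIN}..{BEHAVIOR_MAX}"
            )
        return zi.astype(np.int64)

    resp_col = schema["responded_wave2"]
    if resp_col in cov.columns:
        responded = cov[resp_col].astype(int).to_numpy().astype(bool)
    else:
        responded = np.ones(n, dtype=bool)

    cov_data = {}
    for name, dtype in KNOWN_COVARIATES.items():
        col = schema.get(name, name)
        if col in cov.columns:
            cov_data[name] = cov[col].astype(dtype).to_numpy()
    covariates = pd.DataFrame(cov_data, index=pd.Index(ids, name="actor_id"))

    return SchoolPanel(
        school_id=school_id,
        actor_ids=ids,
        wave1=mats[0],
        wave2=mats[1],
        behavior1=_behavior("behavior_wave1"),
        behavior2=_behavior("behavior_wave2"),
        covariates=covariates,
        responded_wave2=responded,
    )


def write_panel(panel: SchoolPanel, directory, schema: dict | None = None) -> dict:
    """Write a panel back to the edge-list/covariate format ``read_panel`` reads.

    Returns the paths written.  The imputation flags are not serialized: a
    written panel reads back as observed data, and ``impute_locf`` is
    deterministic, so an imputed panel round-trips via read + re-impute.
    """
    import pathlib

    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for wave, x in (("wave1", panel.wave1), ("wave2", panel.wave2)):
        rows = [
            {schema["source"]: panel.actor_ids[i], schema["target"]: panel.actor_ids[j]}
            for i, j in zip(*np.nonzero(x))
        ]
        path = directory / f"{panel.school_id}_{wave}_edges.csv"
        pd.DataFrame(rows, columns=[schema["source"], schema["target"]]).to_csv(
            path, index=False
        )
        paths[wave] = path
    cov = panel.covariates.copy()
    cov.insert(0, schema["actor_id"], panel.actor_ids)
    cov[schema["behavior_wave1"]] = panel.behavior1
    cov[schema["behavior_wave2"]] = panel.behavior2
    cov[schema["responded_wave2"]] = panel.responded_wave2.astype(int)
    cov_path = directory / f"{panel.school_id}_covariates.csv"
    cov.to_csv(cov_path, index=False)
    paths["covariates"] = cov_path
    return paths


def to_pajek(panel: SchoolPanel, path, wave: int = 1) -> None:
    """Export one wave of the friendship network in Pajek .net format."""
    x = panel.wave1 if wave == 1 else panel.wave2
    lines = [f"*Vertices {panel.n_actors}"]
    lines += [f'{i + 1} "{a}"' for i, a in enumerate(panel.actor_ids)]
    lines.append("*Arcs")
    lines += [f"{i + 1} {j + 1}" for i, j in zip(*np.nonzero(x))]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
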