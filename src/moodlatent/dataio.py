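"""Reading, matrix assembly and per-participant centering of longitudinal
questionnaire responses.

Data flow
---------
Responses live in a long-format CSV (one row per item response)::

    participant_id,cohort,date,questionnaire,item,value
    BD-001,BD,2014-01-01,MZ,anxious,3

:func:`read_responses` parses and validates the file into a
:class:`LongitudinalDataset`.  :func:`build_matrix` slices one
instrument/cohort, applies listwise deletion (a record with any missing
item is dropped whole) and pivots to a samples x items matrix; QIDS records
are collapsed to their 9 domain scores so the QIDS matrix has 9 columns.
:func:`center_by_participant` subtracts each participant's own item means,
removing individual reporting bias — the same mood level may be scored
differently by different people, so raw item scores are not comparable
across participants.  Centering turns the discrete Likert matrix into a
continuous one and is the preprocessing step the latent-variable analysis
assumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import EmptyMatrixError, ParseError, ValidationError
from .questionnaires import DEFAULT_SPECS, QuestionnaireSpec, qids_domain_scores

logger = logging.getLogger(__name__)

__all__ = [
    "LongitudinalDataset",
    "RawMatrix",
    "CenteredMatrix",
    "read_responses",
    "build_matrix",
    "center_by_participant",
]

CSV_COLUMNS = ["participant_id", "cohort", "date", "questionnaire", "item", "value"]


@dataclass
class LongitudinalDataset:
    """Long-format longitudinal item responses.

    ``frame`` has one row per (participant, date, questionnaire, item)
    response with columns ``participant_id, cohort, date, questionnaire,
    item, value``.  A record is the set of rows sharing
    (participant_id, date, questionnaire); absent items simply have no row.
    """

    frame: pd.DataFrame
    specs: Mapping[str, QuestionnaireSpec]

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.frame["cohort"].unique())

    @property
    def instruments(self) -> list[str]:
        return sorted(self.frame["questionnaire"].unique())

    @property
    def n_records(self) -> int:
        if self.frame.empty:
            return 0
        return len(
            self.frame.drop_duplicates(
                ["participant_id", "date", "questionnaire"]
            )
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, columns=CSV_COLUMNS)

    @classmethod
    def from_csv(cls, path, specs: Mapping[str, QuestionnaireSpec] | None = None
                 ) -> "LongitudinalDataset":
        return read_responses(path, specs=specs)


def read_responses(
    path,
    specs: Mapping[str, QuestionnaireSpec] | None = None,
) -> LongitudinalDataset:
    """Parse and validate a long-format response CSV.

    Unknown instruments or items and out-of-range values are rejected with
    the 1-based line number of the first offending row.  An empty file (header
    only) yields an empty dataset with a logged warning.
    """
    specs = dict(specs) if specs is not None else dict(DEFAULT_SPECS)
    try:
        frame = pd.read_csv(path, dtype={"participant_id": str, "item": str})
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing_cols = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing columns {missing_cols}")
    frame = frame[CSV_COLUMNS].copy()
    if frame.empty:
        logger.warning("%s: no response rows (header only)", path)
        frame["date"] = pd.to_datetime(frame["date"])
        return LongitudinalDataset(frame=frame, specs=specs)

    # +2: 1-based line numbers counting the header line.
    lines = frame.index.to_numpy() + 2

    try:
        frame["date"] = pd.to_datetime(frame["date"], format="ISO8601")
    except (ValueError, TypeError):
        parsed = pd.to_datetime(frame["date"], errors="coerce", format="ISO8601")
        bad = int(lines[parsed.isna().to_numpy()][0])
        raise ParseError(f"{path}: line {bad}: unparseable ISO-8601 date")

    values = pd.to_numeric(frame["value"], errors="coerce")
    nonint = values.isna() | (values != values.round())
    if nonint.any():
        bad = int(lines[nonint.to_numpy()][0])
        raise ParseError(f"{path}: line {bad}: non-integer value")
    frame["value"] = values.astype(int)

    unknown_q = ~frame["questionnaire"].isin(specs.keys())
    if unknown_q.any():
        bad = int(lines[unknown_q.to_numpy()][0])
        name = frame.loc[unknown_q, "questionnaire"].iloc[0]
        raise ParseError(f"{path}: line {bad}: unknown instrument {name!r}")

    for name, spec in specs.items():
        mask = (frame["questionnaire"] == name).to_numpy()
        if not mask.any():
            continue
        sub = frame.loc[mask]
        bad_item = ~sub["item"].isin(spec.items)
        if bad_item.any():
            bad = int(lines[mask][bad_item.to_numpy()][0])
            item = sub.loc[bad_item, "item"].iloc[0]
            raise ParseError(
                f"{path}: line {bad}: unknown {name} item {item!r}"
            )
        out = (sub["value"] < spec.scale_min) | (sub["value"] > spec.scale_max)
        if out.any():
            bad = int(lines[mask][out.to_numpy()][0])
            value = sub.loc[out, "value"].iloc[0]
            raise ValidationError(
                f"{path}: line {bad}: {name} value {value} outside "
                f"[{spec.scale_min}, {spec.scale_max}]"
            )
    return LongitudinalDataset(frame=frame, specs=specs)


@dataclass
class RawMatrix:
    """An instrument/cohort data matrix before centering.

    ``X`` is integer-valued (QIDS: domain scores), one row per complete
    record, rows ordered by (participant_id, date).
    """

    X: np.ndarray
    item_names: tuple[str, ...]
    row_provenance: pd.DataFrame  # columns: participant_id, date
    instrument: str
    cohort: str


@dataclass
class CenteredMatrix:
    """Per-participant mean-centered data matrix.

    ``X[n, m] = raw[n, m] - mean_m(participant of row n)``; the subtracted
    means are kept in ``participant_means`` (participant_id x item) so the
    raw matrix can be reconstructed exactly.
    """

    X: np.ndarray
    item_names: tuple[str, ...]
    row_provenance: pd.DataFrame
    participant_means: pd.DataFrame
    instrument: str = ""
    cohort: str = ""

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_items(self) -> int:
        return self.X.shape[1]

    def reconstruct_raw(self) -> np.ndarray:
        """Invert the centering: add each participant's means back."""
        means = self.participant_means.loc[
            self.row_provenance["participant_id"]
        ].to_numpy()
        return self.X + means

    def to_frame(self) -> pd.DataFrame:
        """Centered matrix as a DataFrame with provenance columns."""
        out = self.row_provenance.reset_index(drop=True).copy()
        for j, name in enumerate(self.item_names):
            out[name] = self.X[:, j]
        return out


def build_matrix(
    dataset: LongitudinalDataset,
    questionnaire: str,
    cohort: str | None = None,
) -> RawMatrix:
    """Assemble the samples x items matrix for one instrument (and cohort).

    Listwise deletion: records missing any item are dropped whole.  QIDS
    records are collapsed to the 9 domain scores via the max-mapping, so the
    QIDS matrix columns are domain names.  Duplicate (participant, date)
    records keep the last occurrence with a logged warning.
    """
    spec = dataset.specs.get(questionnaire)
    if spec is None:
        raise ValidationError(f"unknown instrument {questionnaire!r}")
    frame = dataset.frame
    mask = frame["questionnaire"] == questionnaire
    if cohort is not None:
        mask &= frame["cohort"] == cohort
    sub = frame.loc[mask]
    if sub.empty:
        raise EmptyMatrixError(
            f"no records for instrument {questionnaire!r}"
            + (f", cohort {cohort!r}" if cohort is not None else "")
        )

    dup = sub.duplicated(["participant_id", "date", "item"], keep="last")
    if dup.any():
        logger.warning(
            "%s/%s: %d duplicate item rows; keeping the last occurrence",
            questionnaire, cohort, int(dup.sum()),
        )
        sub = sub.loc[~dup]

    wide = sub.pivot(
        index=["participant_id", "date"], columns="item", values="value"
    )
    # Listwise deletion over the instrument's full item set.
    for item in spec.items:
        if item not in wide.columns:
            wide[item] = np.nan
    wide = wide[list(spec.items)].dropna(axis=0, how="any")
    if wide.empty:
        raise EmptyMatrixError(
            f"no complete records for instrument {questionnaire!r}"
            + (f", cohort {cohort!r}" if cohort is not None else "")
        )
    wide = wide.sort_index()

    X = wide.to_numpy(dtype=float)
    if spec.domain_map is not None:
        cols = {item: i for i, item in enumerate(spec.items)}
        domains = []
        for _, subset in spec.domain_map:
            idx = [cols[i] for i in subset]
            domains.append(X[:, idx].max(axis=1))
        X = np.column_stack(domains)
        item_names = spec.matrix_columns
    else:
        item_names = spec.items

    provenance = wide.index.to_frame(index=False)
    return RawMatrix(
        X=X.astype(float),
        item_names=tuple(item_names),
        row_provenance=provenance,
        instrument=questionnaire,
        cohort=cohort if cohort is not None else "all",
    )


def center_by_participant(
    raw: RawMatrix,
    min_records_per_participant: int = 1,
) -> CenteredMatrix:
    """Subtract each participant's per-item mean from their rows.

    Removes individual reporting bias so item scores are comparable across
    participants.  Participants with fewer than
    ``min_records_per_participant`` records are dropped (default 1 keeps
    everyone; a single-record participant centers to an all-zero row).
    """
    if raw.X.size == 0:
        raise EmptyMatrixError("cannot center an empty matrix")
    prov = raw.row_provenance.reset_index(drop=True)
    pid = prov["participant_id"]
    if min_records_per_participant > 1:
        counts = pid.map(pid.value_counts())
        keep = (counts >= min_records_per_participant).to_numpy()
        if not keep.any():
            raise EmptyMatrixError(
                "no participant has >= "
                f"{min_records_per_participant} records"
            )
        prov = prov.loc[keep].reset_index(drop=True)
        raw_X = raw.X[keep]
        pid = prov["participant_id"]
    else:
        raw_X = raw.X

    df = pd.DataFrame(raw_X, columns=list(raw.item_names))
    means = df.groupby(pid.to_numpy()).transform("mean").to_numpy()
    participant_means = (
        df.assign(participant_id=pid.to_numpy())
        .groupby("participant_id")
        .mean()
    )
    return CenteredMatrix(
        X=raw_X - means,
        item_names=raw.item_names,
        row_provenance=prov,
        participant_means=participant_means,
        instrument=raw.instrument,
        cohort=raw.cohort,
    )
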