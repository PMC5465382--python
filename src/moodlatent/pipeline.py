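"""End-to-end analysis: matrices, centering, dense and sparse PCA per
instrument and cohort, and cross-cohort divergence where the sparse
structure is comparable.

For each instrument and cohort the pipeline builds the complete-record
matrix, centers it per participant, fits dense PCA (the baseline whose
all-nonzero loadings motivate sparsity) and sparse PCA, and records the
cardinality-variance trade-off path of the first component.  When an
instrument's sparse supports are *identical across cohorts* — the
precondition for comparing like with like — per-component cohort score
samples are compared with KS tests and symmetric KL divergences.
Components are matched across cohorts by their support item sets (cohorts
may extract the same components in different order), labelled by their
support items, and presented in the first cohort's component order.

An optional merged mode concatenates the three weekly instruments
(ASRM + QIDS domains + GAD-7 = 21 columns) aligned by participant and ISO
week, listwise-deleting weeks where any instrument is absent, and fits
SPCA per cohort on the combined matrix.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .compare import DivergenceReport, divergence_report
from .dataio import (
    CenteredMatrix,
    LongitudinalDataset,
    build_matrix,
    center_by_participant,
)
from .exceptions import EmptyMatrixError, InsufficientDataError, MoodLatentError
from .latent import ComponentSet, DensePCA, SparsePCA, cardinality_path

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "AnalysisReport", "run", "merged_instrument_fit",
           "write_report"]

WEEKLY_MERGE_INSTRUMENTS = ("ASRM", "QIDS", "GAD7")


@dataclass
class AnalysisConfig:
    """Tunable settings of the end-to-end analysis."""

    instruments: tuple[str, ...] | None = None   # None = all in the dataset
    cohorts: tuple[str, ...] | None = None
    n_components: int = 3
    cardinality: int | tuple[int, ...] | str = 2
    auto_variance_fraction: float = 0.9
    restarts: int = 8
    bandwidth_rule: str | float = "silverman"
    kl_variant: str = "sum"
    loadings_mode: str = "per_cohort"            # or "pooled"
    min_records_per_participant: int = 1
    compute_cardinality_paths: bool = True
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class InstrumentCohortResult:
    """All fitted objects for one instrument x cohort slice."""

    instrument: str
    cohort: str
    centered: CenteredMatrix
    dense: ComponentSet
    sparse: ComponentSet
    cardinality_path: list[tuple[int, float]] | None = None


@dataclass
class AnalysisReport:
    """Full pipeline output.

    ``results[(instrument, cohort)]`` holds the per-slice fits;
    ``divergence[instrument]`` the cross-cohort comparison for instruments
    whose sparse supports coincide across cohorts; ``metadata`` the seed,
    config hash and sample counts.
    """

    results: dict[tuple[str, str], InstrumentCohortResult]
    divergence: dict[str, DivergenceReport]
    metadata: dict

    def sparse_supports(self, instrument: str) -> dict[str, list[set[str]]]:
        """Per-cohort sparse support item-sets, in component order."""
        out = {}
        for (inst, cohort), res in self.results.items():
            if inst == instrument:
                out[cohort] = [
                    set(res.sparse.support_items(i))
                    for i in range(res.sparse.n_components)
                ]
        return out

    def supports_consistent(self, instrument: str) -> bool:
        """True when every cohort extracts the same sparse supports
        (possibly in different order)."""
        per_cohort = self.sparse_supports(instrument)
        if len(per_cohort) < 2:
            return False
        sets = [
            {frozenset(s) for s in supports}
            for supports in per_cohort.values()
        ]
        return all(s == sets[0] for s in sets[1:])


def _component_label(items: Sequence[str]) -> str:
    return "+".join(items)


def run(
    dataset: LongitudinalDataset,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the full analysis over a longitudinal dataset.

    Deterministic given ``config.seed``.  Any stage failure raises a
    :class:`MoodLatentError` whose message names the failing
    instrument/cohort stage.
    """
    config = config if config is not None else AnalysisConfig()
    instruments = (
        list(config.instruments) if config.instruments is not None
        else dataset.instruments
    )
    cohorts = (
        list(config.cohorts) if config.cohorts is not None
        else dataset.cohorts
    )

    results: dict[tuple[str, str], InstrumentCohortResult] = {}
    counts: dict[str, dict[str, int]] = {}
    for instrument in instruments:
        counts[instrument] = {}
        for cohort in cohorts:
            stage = f"{instrument}/{cohort}"
            try:
                raw = build_matrix(dataset, instrument, cohort)
                centered = center_by_participant(
                    raw, config.min_records_per_participant
                )
                dense = DensePCA(
                    n_components=config.n_components
                ).fit(centered).to_component_set(centered)
                spca = SparsePCA(
                    n_components=config.n_components,
                    cardinality=config.cardinality,
                    auto_variance_fraction=config.auto_variance_fraction,
                    restarts=config.restarts,
                    random_state=config.seed,
                ).fit(centered)
                sparse = spca.to_component_set(centered)
                path = None
                if config.compute_cardinality_paths:
                    path = cardinality_path(
                        centered, 0,
                        cardinality=config.cardinality
                        if not isinstance(config.cardinality, str) else 2,
                        restarts=config.restarts,
                        random_state=config.seed,
                    )
            except MoodLatentError as exc:
                raise type(exc)(f"stage {stage}: {exc}") from exc
            results[(instrument, cohort)] = InstrumentCohortResult(
                instrument=instrument,
                cohort=cohort,
                centered=centered,
                dense=dense,
                sparse=sparse,
                cardinality_path=path,
            )
            counts[instrument][cohort] = centered.n_samples

    report = AnalysisReport(
        results=results,
        divergence={},
        metadata={
            "package_version": _pkg_version,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "sample_counts": counts,
            "instruments": instruments,
            "cohorts": cohorts,
        },
    )

    if len(cohorts) >= 2:
        for instrument in instruments:
            if report.supports_consistent(instrument):
                report.divergence[instrument] = _compare_cohorts(
                    report, instrument, cohorts, config
                )
            else:
                logger.info(
                    "%s: sparse supports differ across cohorts; "
                    "skipping divergence comparison", instrument,
                )
    return report


def _compare_cohorts(
    report: AnalysisReport,
    instrument: str,
    cohorts: Sequence[str],
    config: AnalysisConfig,
) -> DivergenceReport:
    """KS + symmetric-KL comparison of per-component cohort scores.

    Components are matched across cohorts by support set and ordered as in
    the first cohort.  ``loadings_mode="per_cohort"`` scores each cohort on
    its own fitted loadings (the default; supports coincide, weights may
    differ slightly); ``"pooled"`` applies the first cohort's loadings to
    every cohort.
    """
    first = report.results[(instrument, cohorts[0])]
    scores_by_component: dict[str, dict[str, np.ndarray]] = {}
    for i in range(first.sparse.n_components):
        support = frozenset(first.sparse.support_items(i))
        label = _component_label(sorted(support))
        scores: dict[str, np.ndarray] = {}
        for cohort in cohorts:
            res = report.results[(instrument, cohort)]
            if config.loadings_mode == "pooled":
                w = first.sparse.loadings[i]
                scores[cohort] = res.centered.X @ w
            else:
                j = next(
                    jj for jj in range(res.sparse.n_components)
                    if frozenset(res.sparse.support_items(jj)) == support
                )
                scores[cohort] = res.sparse.scores[:, j]
        scores_by_component[label] = scores
    return divergence_report(
        scores_by_component,
        kl_variant=config.kl_variant,
        bandwidth_rule=config.bandwidth_rule,
    )


# ---------------------------------------------------------------------------
# Merged weekly-instrument fit
# ---------------------------------------------------------------------------

def merged_instrument_fit(
    dataset: LongitudinalDataset,
    config: AnalysisConfig | None = None,
    instruments: Sequence[str] = WEEKLY_MERGE_INSTRUMENTS,
) -> dict[str, ComponentSet]:
    """Sparse PCA per cohort on the concatenated weekly instruments.

    Records from the listed instruments are aligned by (participant, ISO
    week); weeks where any instrument lacks a complete record are listwise
    deleted.  The resulting matrix has the instruments' columns side by
    side (5 + 9 + 7 = 21 for ASRM + QIDS domains + GAD-7) and is centered
    per participant before fitting.
    """
    config = config if config is not None else AnalysisConfig()
    cohorts = (
        list(config.cohorts) if config.cohorts is not None
        else dataset.cohorts
    )
    out: dict[str, ComponentSet] = {}
    for cohort in cohorts:
        frames = []
        all_columns: list[str] = []
        for instrument in instruments:
            raw = build_matrix(dataset, instrument, cohort)
            iso = pd.to_datetime(
                raw.row_provenance["date"]
            ).dt.isocalendar()
            key = pd.DataFrame(
                {
                    "participant_id": raw.row_provenance["participant_id"],
                    "week": iso["year"].astype(str) + "-W"
                    + iso["week"].astype(str).str.zfill(2),
                }
            )
            cols = [f"{instrument}:{c}" for c in raw.item_names]
            df = pd.concat(
                [key, pd.DataFrame(raw.X, columns=cols)], axis=1
            )
            # One record per participant-week: keep the last.
            df = df.drop_duplicates(["participant_id", "week"], keep="last")
            frames.append(df.set_index(["participant_id", "week"]))
            all_columns.extend(cols)
        merged = pd.concat(frames, axis=1, join="inner").dropna()
        if merged.empty:
            raise EmptyMatrixError(
                f"cohort {cohort!r}: no overlapping weeks across "
                f"{list(instruments)}"
            )
        merged = merged.sort_index()
        prov = merged.index.to_frame(index=False).rename(
            columns={"week": "date"}
        )
        from .dataio import RawMatrix

        raw_merged = RawMatrix(
            X=merged.to_numpy(dtype=float),
            item_names=tuple(all_columns),
            row_provenance=prov,
            instrument="+".join(instruments),
            cohort=cohort,
        )
        centered = center_by_participant(
            raw_merged, config.min_records_per_participant
        )
        est = SparsePCA(
            n_components=config.n_components,
            cardinality=config.cardinality,
            auto_variance_fraction=config.auto_variance_fraction,
            restarts=config.restarts,
            random_state=config.seed,
        ).fit(centered)
        out[cohort] = est.to_component_set(centered)
    return out


# ---------------------------------------------------------------------------
# Report emission
# ---------------------------------------------------------------------------

def write_report(report: AnalysisReport, outdir) -> None:
    """Write loading tables (CSV, exact zeros for excluded items),
    divergence tables and a JSON manifest to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (instrument, cohort), res in report.results.items():
        prefix = f"{instrument}_{cohort}"
        res.dense.loading_table().to_csv(outdir / f"{prefix}_pca.csv")
        res.sparse.loading_table().to_csv(outdir / f"{prefix}_spca.csv")
        if res.cardinality_path is not None:
            pd.DataFrame(
                res.cardinality_path, columns=["k", "variance_pct"]
            ).to_csv(outdir / f"{prefix}_cardinality_path.csv", index=False)
    for instrument, div in report.divergence.items():
        div.to_table().to_csv(outdir / f"{instrument}_divergence.csv")
        div.pairwise.to_csv(
            outdir / f"{instrument}_divergence_pairs.csv", index=False
        )
        div.summaries.to_csv(
            outdir / f"{instrument}_score_summaries.csv", index=False
        )
    manifest = dict(report.metadata)
    manifest["divergence_instruments"] = sorted(report.divergence)
    manifest["sparse_supports"] = {
        instrument: {
            cohort: [sorted(s) for s in supports]
            for cohort, supports in report.sparse_supports(instrument).items()
        }
        for instrument in report.metadata["instruments"]
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
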