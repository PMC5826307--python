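"""End-to-end wiring: clouds -> feature table -> classification -> HAM.

Convenience layer used by the CLI, the tests and the reproduction script;
all substance lives in the per-stage modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .ci import CI_COLUMNS, compute_ci_features
from .classify import ClassificationReport, SVMConfig, loocv_svm, manova_gate
from .frame import build_crown_frame
from .ham import (
    HAMAssignment,
    HAMKnowledge,
    assign_ham,
    gaussian_summary,
    habits_for,
    load_knowledge,
    species_center,
)
from .io import TreeCloud
from .te import TE_COLUMNS, compute_te_features

__all__ = [
    "FEATURE_COLUMNS",
    "features_for_stand",
    "IdentificationResult",
    "run_identification",
]

FEATURE_COLUMNS = CI_COLUMNS + TE_COLUMNS


def features_for_stand(
    clouds: list[TreeCloud],
    voxel_size: float = 0.5,
    n_layers: int = 8,
    grid_cell: float = 0.5,
    alpha: float = 0.5,
) -> pd.DataFrame:
    """Compute the full 13 CI + 10 TE feature table for a list of clouds."""
    rows = []
    for cloud in clouds:
        frame = build_crown_frame(cloud, voxel_size=voxel_size, n_layers=n_layers)
        row: dict[str, object] = {"tree_id": cloud.tree_id, "species": cloud.species}
        row.update(compute_ci_features(frame, alpha=alpha).as_dict())
        row.update(compute_te_features(cloud, frame, grid_cell=grid_cell).as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=["tree_id", "species", *FEATURE_COLUMNS])


@dataclass
class IdentificationResult:
    """Classification report plus per-species HAM assignments and summaries."""

    report: ClassificationReport
    manova_p: float
    assignments: dict[str, HAMAssignment]
    habits: dict[str, dict[str, str]]
    centers: dict[str, tuple[float, float]]
    summary: pd.DataFrame  # Gaussian mu/sigma divergence table


def run_identification(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    pair: tuple[str, str] | None = None,
    knowledge: HAMKnowledge | None = None,
    svm: SVMConfig | None = None,
    rule: str = "nearest_center",
    scope: str = "all_assigned",
) -> IdentificationResult:
    """Classify species by LOOCV-SVM, then identify each species' HAM.

    ``columns`` defaults to all feature columns present; ``pair`` defaults
    to the knowledge base's feature pair.
    """
    knowledge = knowledge or load_knowledge()
    pair = pair or knowledge.feature_pair
    if columns is None:
        columns = [c for c in table.columns if c in FEATURE_COLUMNS]
    try:
        manova_p = manova_gate(table, columns)
    except ValueError as exc:  # underdetermined gate: report, never block
        warnings.warn(f"MANOVA gate skipped: {exc}")
        manova_p = float("nan")
    report = loocv_svm(table, columns, svm=svm)
    assignments: dict[str, HAMAssignment] = {}
    habits: dict[str, dict[str, str]] = {}
    centers: dict[str, tuple[float, float]] = {}
    for sp in report.confusion.index:
        try:
            center = species_center(
                table, sp, pair, scope=scope, predictions=report.predictions
            )
        except ValueError:
            continue  # species never predicted: no centre to place
        a = assign_ham(center, knowledge, rule=rule, species=sp)
        assignments[sp] = a
        habits[sp] = habits_for(a.assigned, knowledge)
        centers[sp] = center
    summary = gaussian_summary(table, report.predictions, list(pair))
    return IdentificationResult(
        report=report,
        manova_p=manova_p,
        assignments=assignments,
        habits=habits,
        centers=centers,
        summary=summary,
    )
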