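"""Docking-score-weighted prediction of disease indications.

A compound is linked to a disease through the protein targets that (a)
the compound hits with an admissible docking score and (b) the
target–disease map associates with the disease. The prediction
coefficient is the sum of the admissible docking scores over those
shared targets:

    coefficient(c, d) = sum over t in targets(d) with admissible (c, t)
                        of score(c, t)

This additive form is a reconstruction: it is weighted by docking score,
is additive over disjoint target sets, and on realistic score scales
(threshold 9, scores ~9-11) yields coefficients of a few tens for
compounds hitting several disease targets. Alternative weightings
(normalization by the disease's target count, disease priors) are not
applied.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .network import admissible_edges, edges_to_frame

logger = logging.getLogger(__name__)

PREDICTION_COLUMNS = ["compound_id", "disease", "coefficient", "n_supporting_targets"]


def read_disease_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"target_id", "disease"} - set(df.columns)
    if missing:
        raise ValueError(f"disease map missing columns: {sorted(missing)}")
    return df.drop_duplicates(["target_id", "disease"]).reset_index(drop=True)


def predict_indications(
    edges,
    reference_scores: Mapping[str, float] | pd.DataFrame,
    disease_links: pd.DataFrame,
    threshold: float = 9.0,
) -> pd.DataFrame:
    """Rank (compound, disease) pairs by summed admissible docking scores.

    Parameters
    ----------
    edges
        Docking score table (or edge list) shared with the network stage.
    reference_scores
        Per-target reference-ligand scores for the admissibility rule.
    disease_links
        Two-column table (``target_id``, ``disease``); duplicate rows are
        collapsed, and rows naming targets absent from the score table are
        counted and ignored with a warning.
    threshold
        Global docking-score cutoff (strict, applied together with the
        per-target reference bar).

    Returns
    -------
    DataFrame with columns ``compound_id, disease, coefficient,
    n_supporting_targets``, sorted by coefficient descending with ties
    broken by compound id then disease. Pairs with zero coefficient are
    omitted.
    """
    all_edges = edges_to_frame(edges)
    links = disease_links.drop_duplicates(["target_id", "disease"])
    known_targets = set(all_edges["target_id"])
    unknown = links[~links["target_id"].isin(known_targets)]
    if len(unknown):
        logger.warning(
            "disease map references %d link(s) to targets absent from the score table; ignored",
            len(unknown),
        )
        links = links[links["target_id"].isin(known_targets)]

    adm = admissible_edges(all_edges, threshold, reference_scores)
    if adm.empty or links.empty:
        return pd.DataFrame(columns=PREDICTION_COLUMNS)

    joined = adm.merge(links, on="target_id")
    table = (
        joined.groupby(["compound_id", "disease"], as_index=False)
        .agg(coefficient=("score", "sum"), n_supporting_targets=("target_id", "nunique"))
    )
    table = table[table["coefficient"] > 0]
    table = table.sort_values(
        ["coefficient", "compound_id", "disease"], ascending=[False, True, True], ignore_index=True
    )
    return table[PREDICTION_COLUMNS]


def top_predictions(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """First *k* rows of the stable prediction ranking."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return table.head(k).reset_index(drop=True)
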