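"""Network scores: loading-weighted sums of standardized intakes, tertiled.

Each dietary network gets a per-subject score: the first-principal-component
factor loadings of the network's food-group columns weight the standardized
intakes, which are then summed. Scores are categorized into tertiles (T1 =
lowest) for the association analysis, so any positive rescaling of the
loadings is inert.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .communities import DietaryNetwork
from .ggm import sample_correlation

__all__ = ["LoadingVector", "pca_loadings", "network_score", "assign_tertiles", "score_networks"]

TERTILE_LABELS = ("T1", "T2", "T3")


@dataclasses.dataclass
class LoadingVector:
    """First-PC factor loadings for a network's food groups.

    Loadings are the leading eigenvector of the groups' correlation matrix
    scaled by the square root of its eigenvalue (factor-loading convention),
    oriented so the network's central food loads nonnegatively.
    """

    network: str
    loadings: dict  # group -> signed loading
    explained_eigenvalue: float


def pca_loadings(
    standardized: pd.DataFrame,
    network: DietaryNetwork,
    *,
    degeneracy_tol: float = 1e-8,
    min_nodes: int = 3,
) -> LoadingVector:
    """First-principal-component loadings of a network's intake columns."""
    cols = [c for c in standardized.columns if c in set(network.nodes)]
    missing = set(network.nodes) - set(cols)
    if missing:
        raise ValueError(f"network columns absent from intake table: {sorted(missing)}")
    if len(cols) < min_nodes:
        raise ValueError(f"network has {len(cols)} columns; need >= {min_nodes}")
    if standardized.shape[0] <= len(cols):
        raise ValueError("need more subjects than network food groups for PCA")

    corr = sample_correlation(standardized[cols])
    eigvals, eigvecs = np.linalg.eigh(corr)
    lead, second = eigvals[-1], eigvals[-2]
    if lead - second < degeneracy_tol:
        raise ValueError(
            f"degenerate leading eigenvalue ({lead:.6g} vs {second:.6g}); loadings undefined"
        )
    vec = eigvecs[:, -1] * np.sqrt(lead)

    anchor = network.central[0] if network.central else cols[0]
    if vec[cols.index(anchor)] < 0:
        vec = -vec
    return LoadingVector(network=network.name, loadings=dict(zip(cols, vec)), explained_eigenvalue=float(lead))


def network_score(standardized: pd.DataFrame, loadings: LoadingVector) -> pd.Series:
    """Per-subject score: sum over network foods of loading * z-intake."""
    cols = list(loadings.loadings)
    missing = [c for c in cols if c not in standardized.columns]
    if missing:
        raise ValueError(f"standardized table lacks network columns: {missing}")
    weights = np.array([loadings.loadings[c] for c in cols])
    scores = standardized[cols].to_numpy() @ weights
    return pd.Series(scores, index=standardized.index, name=f"{loadings.network}_score")


def assign_tertiles(scores: pd.Series) -> pd.Series:
    """Rank-based tertiles T1 < T2 < T3 with near-equal group sizes.

    The stable sort sends tied scores to the lower tertile in input order;
    when n is not divisible by 3 the remainder goes to the lower tertiles,
    so sizes differ by at most one subject.
    """
    n = len(scores)
    if n < 3:
        raise ValueError("need at least 3 subjects for tertiles")
    values = np.asarray(scores, dtype=float)
    if np.all(values == values[0]):
        raise ValueError("all scores identical; tertiles undefined")
    order = np.argsort(values, kind="stable")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if t < rem else 0) for t in range(3)]
    labels = np.empty(n, dtype=object)
    start = 0
    for t, size in enumerate(sizes):
        labels[order[start : start + size]] = TERTILE_LABELS[t]
        start += size
    name = str(scores.name).replace("_score", "") if scores.name else "score"
    return pd.Series(labels, index=scores.index, name=f"{name}_tertile")


def score_networks(
    standardized: pd.DataFrame, networks: list[DietaryNetwork]
) -> tuple[pd.DataFrame, dict]:
    """Score every network; returns (score/tertile table, loadings by name)."""
    columns = {}
    loadings_by_network = {}
    for net in networks:
        lv = pca_loadings(standardized, net)
        net.loadings = lv.loadings
        scores = network_score(standardized, lv)
        columns[scores.name] = scores
        columns[f"{net.name}_tertile"] = assign_tertiles(scores)
        loadings_by_network[net.name] = lv
    return pd.DataFrame(columns, index=standardized.index), loadings_by_network
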