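"""Environmental-variable screening: impurity importance + correlation filter.

Site and climate variables are ranked by random-forest impurity importance
(for a continuous response the split criterion is variance reduction — the
regression analogue of the Gini decrease used for classification; this is
worth stating plainly because the field's shorthand for both is "Gini
importance").  Within each group, strongly correlated pairs (|r| > 0.7)
are then resolved by keeping the more important member.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .datamodel import SITE_COLUMNS, Dataset

#: The screened variable sets of the Chinese-fir study, used as the default
#: ladder inputs downstream.
STUDY_SITE_VARS = ("PW", "HB", "TRHD", "PX", "DM")
STUDY_CLIM_VARS = ("DD18", "MAP", "Eref")


@dataclass(frozen=True)
class ImportanceRanking:
    """Normalized impurity importances, descending."""

    group: str                                  # "Site" or "Clim"
    entries: tuple[tuple[str, float], ...]      # (variable, importance in [0,1])

    def __post_init__(self) -> None:
        values = [v for _, v in self.entries]
        if values and abs(sum(values) - 1.0) > 1e-6:
            raise ValueError("importances must sum to 1 within the group")
        if any(b > a + 1e-12 for (_, a), (_, b)
               in zip(self.entries, self.entries[1:])):
            raise ValueError("entries must be in descending importance order")

    @property
    def variables(self) -> list[str]:
        return [name for name, _ in self.entries]

    def importance(self, name: str) -> float:
        return dict(self.entries)[name]

    def top(self, k: int) -> "ImportanceRanking":
        """Leading ``k`` entries, renormalized to sum to 1."""
        head = self.entries[:k]
        total = sum(v for _, v in head)
        if total == 0:
            share = 1.0 / len(head)
            return ImportanceRanking(self.group,
                                     tuple((n, share) for n, _ in head))
        return ImportanceRanking(self.group,
                                 tuple((n, v / total) for n, v in head))


def impurity_importance(X, y, names, group: str = "Site",
                        n_trees: int = 300, seed: int = 0,
                        absorb=None, min_samples_leaf: int = 40,
                        max_features: float = 0.6) -> ImportanceRanking:
    """Mean-decrease-in-impurity ranking of the columns of ``X``.

    ``absorb`` optionally supplies extra columns (e.g. tree age, or the
    other covariate group) that join the forest so their variance does not
    masquerade as signal of the ranked columns; importances are
    renormalized over ``names`` only.  The forest draws ``max_features`` of
    the predictors per split (letting correlated proxies share credit, as a
    practitioner's mtry does) and uses generous leaves so spurious
    deep-split gains on noise variables stay small.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 30:
        raise ValueError("importance ranking needs at least 30 rows")
    if X.shape[1] < 2:
        raise ValueError("importance ranking needs at least 2 columns")
    names = list(names)
    if len(names) != X.shape[1]:
        raise ValueError("names must match the number of columns")
    if np.std(y) == 0:
        warnings.warn("constant response: importances are uniform", stacklevel=2)
        share = 1.0 / len(names)
        entries = tuple((n, share) for n in names)
        return ImportanceRanking(group, entries)
    design = X
    n_absorb = 0
    if absorb is not None:
        absorb = np.atleast_2d(np.asarray(absorb, dtype=float))
        if absorb.shape[0] != X.shape[0]:
            absorb = absorb.T
        design = np.column_stack([absorb, X])
        n_absorb = absorb.shape[1]
    rf = RandomForestRegressor(n_estimators=n_trees,
                               min_samples_leaf=min(min_samples_leaf,
                                                    max(1, X.shape[0] // 10)),
                               max_features=max_features,
                               random_state=seed)
    rf.fit(design, y)
    raw = rf.feature_importances_[n_absorb:]
    total = raw.sum()
    if total == 0:
        raw = np.full(len(names), 1.0)
        total = float(len(names))
    importances = raw / total
    order = np.argsort(-importances, kind="stable")
    entries = tuple((names[i], float(importances[i])) for i in order)
    return ImportanceRanking(group, entries)


def pearson_matrix(X, names=None) -> pd.DataFrame:
    """Pairwise Pearson r of the columns of ``X`` (diagonal 1).

    Constant columns yield undefined (NaN) entries, flagged with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("Pearson correlation needs at least 3 rows")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    constant = [names[j] for j in range(X.shape[1]) if np.std(X[:, j]) == 0]
    if constant:
        warnings.warn(f"constant columns give undefined correlations: "
                      f"{constant}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=list(names), columns=list(names))


def correlation_screen(ranking: ImportanceRanking, corr: pd.DataFrame,
                       threshold: float = 0.7) -> list[str]:
    """Resolve strongly correlated pairs by importance.

    Pairs with |r| > ``threshold`` are visited in descending |r|; in each
    offending pair whose members both survive so far, the lower-importance
    member is dropped.  A variable eliminated by a proxy that is itself
    dropped a step later would be lost for no reason, so dropped variables
    are then reinstated (in importance order) whenever they are no longer
    strongly correlated with anything retained.  The result is
    deterministic and no retained pair exceeds the threshold.
    """
    variables = ranking.variables
    missing = [v for v in variables if v not in corr.index]
    if missing:
        raise ValueError(f"correlation matrix lacks variables {missing}")

    def r(a: str, b: str) -> float:
        value = float(corr.loc[a, b])
        return abs(value) if np.isfinite(value) else 0.0

    pairs = []
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            if r(a, b) > threshold:
                pairs.append((r(a, b), a, b))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    retained = set(variables)
    for _, a, b in pairs:
        if a in retained and b in retained:
            weaker = a if ranking.importance(a) < ranking.importance(b) else b
            retained.discard(weaker)
    for v in variables:                       # reinstate orphaned drops
        if v not in retained and all(r(v, k) <= threshold for k in retained):
            retained.add(v)
    return [v for v in variables if v in retained]


@dataclass
class SelectionReport:
    site_ranking: ImportanceRanking
    clim_ranking: ImportanceRanking
    site_corr: pd.DataFrame
    clim_corr: pd.DataFrame
    site: list[str]
    clim: list[str]

    def as_dict(self) -> dict:
        return {
            "site_ranking": list(self.site_ranking.entries),
            "clim_ranking": list(self.clim_ranking.entries),
            "site": self.site,
            "clim": self.clim,
            "site_corr": self.site_corr.round(3).to_dict(),
            "clim_corr": self.clim_corr.round(3).to_dict(),
        }


def select_environment(ds: Dataset, top_k: int = 5, threshold: float = 0.7,
                       seed: int = 0, n_trees: int = 300) -> SelectionReport:
    """Full screening pipeline for the Site and Clim variable groups.

    Per group: rank by impurity importance (with tree age absorbed into the
    ranking forest), keep the ``top_k`` most important variables, then apply
    the correlation screen at ``threshold``.
    """
    frame = ds.to_frame()
    y = ds.responses
    site_cols = list(SITE_COLUMNS)
    clim_cols = list(ds.climate_names)
    reports = {}
    for group, columns in (("Site", site_cols), ("Clim", clim_cols)):
        # one forest over age, density and both covariate groups: the
        # other group's variance is then credited to its own variables
        # instead of leaking into this group's ranking
        other = [c for c in site_cols + clim_cols if c not in columns]
        X = frame[columns].to_numpy(dtype=float)
        absorb = frame[["T", "N"] + other].to_numpy(dtype=float)
        ranking = impurity_importance(X, y, columns, group=group,
                                      n_trees=n_trees, seed=seed,
                                      absorb=absorb)
        top = ranking.top(min(top_k, len(columns)))
        corr = pearson_matrix(X, columns)
        retained = correlation_screen(top, corr, threshold)
        reports[group] = (ranking, corr, retained)
    site_ranking, site_corr, site = reports["Site"]
    clim_ranking, clim_corr, clim = reports["Clim"]
    return SelectionReport(site_ranking, clim_ranking, site_corr, clim_corr,
                           site, clim)
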