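"""Mutational-signature analysis over phylogeny branch classes.

De novo signatures are extracted from 96-channel spectra by nonnegative
matrix factorization (best of many random restarts), replaced by their
closest reference counterpart at cosine >= 0.85, and refit to branch-class
spectra with a bootstrapped strict nonnegative least squares: per bootstrap
the column's mutations are resampled, NNLS contributions are computed, and
signatures whose removal barely degrades the reconstruction are dropped
(backward elimination); contributions are averaged over bootstraps.

Branches are merged into three classes relative to the driver clone:
``clonal`` (branches shared by all same-clone driver colonies, i.e. the
root path into the clone MRCA branch), ``subclonal`` (branches inside the
clone) and ``wildtype`` (branches belonging only to wildtype colonies).
Colonies with non-recurrent driver variants are excluded.

The probability that a given signature caused a driver mutation multiplies
each clonal-class contribution by the signature's weight on the driver's
trinucleotide channel and normalizes over signatures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .spectra import CHANNELS, N_CHANNELS, cosine, count_spectrum, spectrum_frame
from .trees import Tree

LOW_CONFIDENCE_MUTATIONS = 50  # refits below this count are flagged


# ---------------------------------------------------------------------------
# extraction


@dataclass
class ExtractionResult:
    signatures: pd.DataFrame        # channels x rank, columns sig1..sigK
    contributions: np.ndarray       # rank x n_columns
    reconstruction_error: float
    per_sample_cosine: dict         # original vs reconstructed, per column
    rank_errors: dict = field(default_factory=dict)


def extract_signatures(
    matrix: pd.DataFrame,
    rank: int = 4,
    n_runs: int = 100,
    seed: int | None = None,
    rank_survey: tuple[int, ...] = (),
) -> ExtractionResult:
    """NMF signature extraction, best of ``n_runs`` random restarts.

    Profiles are normalized to sum 1.  ``rank_survey`` optionally reports
    the best reconstruction error at other candidate ranks (for the
    inflection-point rank choice).  Deterministic given ``seed``.
    """
    from sklearn.decomposition import NMF

    X = matrix.to_numpy(dtype=float)
    nz = (X.sum(axis=0) > 0).sum()
    if rank > X.shape[1]:
        raise ValueError(f"rank {rank} exceeds number of columns {X.shape[1]}")
    if nz < rank:
        raise ValueError("need at least `rank` columns with nonzero totals")
    root = np.random.default_rng(seed)
    run_seeds = root.integers(0, 2**31 - 1, size=n_runs)

    def best_fit(k):
        best = None
        for s in run_seeds:
            model = NMF(
                n_components=k, init="random", random_state=int(s),
                max_iter=600, tol=1e-6,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                W = model.fit_transform(X)
            err = model.reconstruction_err_
            if best is None or err < best[0] - 1e-12:
                best = (err, W, model.components_)
        return best

    err, W, H = best_fit(rank)
    totals = W.sum(axis=0)
    totals[totals == 0] = 1.0
    profiles = W / totals
    contributions = H * totals[:, None]
    recon = W @ H
    per_cos = {
        col: cosine(X[:, j], recon[:, j]) for j, col in enumerate(matrix.columns)
    }
    rank_errors = {k: best_fit(k)[0] for k in rank_survey if k != rank}
    rank_errors[rank] = err
    sigs = pd.DataFrame(
        profiles, index=matrix.index,
        columns=[f"sig{i + 1}" for i in range(rank)],
    )
    return ExtractionResult(
        signatures=sigs,
        contributions=contributions,
        reconstruction_error=float(err),
        per_sample_cosine=per_cos,
        rank_errors=rank_errors,
    )


def match_reference(
    extracted: pd.DataFrame,
    catalog: pd.DataFrame,
    min_cos: float = 0.85,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace extracted profiles by their closest catalog counterpart.

    A profile is replaced iff its best cosine similarity is >= ``min_cos``;
    otherwise it is kept as de novo.  Returns (final signature set, match
    report); two extracted profiles mapping to the same catalog entry are
    collapsed and flagged.
    """
    cat = catalog / catalog.sum(axis=0)
    rows, final = [], {}
    for name in extracted.columns:
        sims = {c: cosine(extracted[name], cat[c]) for c in cat.columns}
        best = max(sims, key=sims.get)
        if sims[best] >= min_cos:
            collapsed = best in final
            final[best] = cat[best].to_numpy()
            rows.append((name, best, sims[best], True, collapsed))
        else:
            final[name] = (extracted[name] / extracted[name].sum()).to_numpy()
            rows.append((name, best, sims[best], False, False))
    report = pd.DataFrame(
        rows, columns=["extracted", "best_match", "cosine", "replaced", "collapsed"]
    )
    return spectrum_frame(final), report


# ---------------------------------------------------------------------------
# strict bootstrapped refit


def _strict_fit(y: np.ndarray, S: np.ndarray, min_fraction: float) -> np.ndarray:
    """NNLS with backward elimination.

    Iteratively drops the signature whose removal least degrades the
    reconstruction until every retained signature contributes at least
    ``min_fraction`` of the column total.
    """
    k = S.shape[1]
    active = list(range(k))
    total = y.sum()
    while True:
        coef, _ = nnls(S[:, active], y)
        weak = [i for i, c in zip(active, coef) if c < min_fraction * total]
        if not weak or len(active) == 1:
            out = np.zeros(k)
            out[active] = coef
            return out
        # drop the candidate whose removal degrades reconstruction least
        best_drop, best_cos = None, -1.0
        for i in weak:
            trial = [a for a in active if a != i]
            c_t, _ = nnls(S[:, trial], y)
            cs = cosine(S[:, trial] @ c_t, y)
            if cs > best_cos:
                best_drop, best_cos = i, cs
        active.remove(best_drop)


@dataclass
class RefitResult:
    absolute: pd.DataFrame   # signatures x columns, mean over bootstraps
    relative: pd.DataFrame
    flags: dict


def refit_contributions(
    spectra: pd.DataFrame,
    signatures: pd.DataFrame,
    n_boots: int = 100,
    seed: int | None = None,
    min_fraction: float = 0.02,
) -> RefitResult:
    """Bootstrapped strict signature refit of each spectrum column.

    Per bootstrap the column's mutations are resampled with replacement
    (multinomial over channels) and strict NNLS is fit; contributions are
    averaged over bootstraps and rescaled so absolute contributions sum to
    the column total.  Zero-total columns yield zero contributions, flagged.
    """
    S = (signatures / signatures.sum(axis=0)).to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    flags = {}
    abs_out = {}
    for col in spectra.columns:
        y = spectra[col].to_numpy(dtype=float)
        total = y.sum()
        if total == 0:
            abs_out[col] = np.zeros(S.shape[1])
            flags[col] = "empty"
            continue
        if total < LOW_CONFIDENCE_MUTATIONS:
            flags[col] = "low_confidence"
        acc = np.zeros(S.shape[1])
        p = y / total
        for _ in range(n_boots):
            yb = rng.multinomial(int(round(total)), p).astype(float)
            acc += _strict_fit(yb, S, min_fraction)
        mean = acc / n_boots
        if mean.sum() > 0:
            mean *= total / mean.sum()
        abs_out[col] = mean
    absolute = pd.DataFrame(abs_out, index=list(signatures.columns))
    totals = absolute.sum(axis=0).replace(0, 1.0)
    relative = absolute / totals
    return RefitResult(absolute=absolute, relative=relative, flags=flags)


# ---------------------------------------------------------------------------
# branch classes


@dataclass
class BranchClasses:
    clonal: list[str]
    subclonal: list[str]
    wildtype: list[str]
    excluded_tips: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return dict(clonal=self.clonal, subclonal=self.subclonal,
                    wildtype=self.wildtype)


def partition_branch_classes(
    tree: Tree,
    clone_tips,
    wildtype_tips=None,
    excluded_tips=(),
) -> BranchClasses:
    """Partition branches into clonal / subclonal / wildtype classes.

    ``clone_tips`` are the colonies of the recurrent driver clone (empty for
    a wildtype-only tree); ``excluded_tips`` are colonies with unique,
    non-recurrent driver variants, whose branches join no class.
    """
    clone = frozenset(clone_tips)
    excluded = frozenset(excluded_tips)
    all_tips = frozenset(tree.tip_names())
    wt = (
        frozenset(wildtype_tips)
        if wildtype_tips is not None
        else all_tips - clone - excluded
    )
    if clone and not clone <= all_tips:
        raise ValueError("clone tips missing from the tree")
    if clone:
        mrca = tree.mrca(sorted(clone))
        if tree.clade_tips(mrca) != clone:
            raise ValueError("ambiguous clone: tips do not form a clade")
    clonal, subclonal, wildtype = [], [], []
    for node in tree.preorder():
        clade = tree.clade_tips(node)
        if clone and clone <= clade:
            clonal.append(node.name)
        elif clone and clade < clone:
            subclonal.append(node.name)
        elif clade <= wt:
            wildtype.append(node.name)
    return BranchClasses(
        clonal=clonal, subclonal=subclonal, wildtype=wildtype,
        excluded_tips=sorted(excluded),
    )


def class_spectra(
    tree: Tree,
    contexts_by_branch: dict[str, list],
    classes: BranchClasses,
) -> pd.DataFrame:
    """Merged 96-channel spectrum per branch class."""
    cols = {}
    for name, branches in classes.as_dict().items():
        ctx = [c for b in branches for c in contexts_by_branch.get(b, [])]
        cols[name] = count_spectrum(ctx)
    return spectrum_frame(cols)


# ---------------------------------------------------------------------------
# cumulative spectrum vs age


def cumulative_age_similarity(
    tree: Tree,
    contexts_by_branch: dict[str, list],
    model,
    ages=range(0, 64),
) -> pd.DataFrame:
    """Cosine of each branch's cumulative root-path spectrum (the branch's
    own mutations included) against the predicted age spectrum.

    Returns one row per (branch, age) plus per-branch argmax age; branches
    with fewer than 50 cumulative mutations are flagged low-confidence.
    """
    ages = list(ages)
    predicted = {a: model.predicted(a) for a in ages}
    spectra = {}
    for node in tree.preorder():
        own = count_spectrum(contexts_by_branch.get(node.name, []))
        parent = spectra[id(node.parent)] if node.parent is not None else 0.0
        spectra[id(node)] = parent + own
    rows = []
    for node in tree.preorder():
        spec = spectra[id(node)]
        total = float(np.sum(spec))
        if total == 0:
            rows.append((node.name, np.nan, np.nan, total, "undefined"))
            continue
        curve = np.array([cosine(spec, predicted[a]) for a in ages])
        argmax = ages[int(np.argmax(curve))]
        flag = "low_confidence" if total < LOW_CONFIDENCE_MUTATIONS else ""
        for a, c in zip(ages, curve):
            rows.append((node.name, a, c, total, flag))
        rows.append((node.name, -1, float(argmax), total, "argmax"))
    return pd.DataFrame(
        rows, columns=["branch", "age", "cosine", "n_mutations", "flag"]
    )


def branch_argmax_ages(similarity: pd.DataFrame) -> pd.Series:
    am = similarity[similarity["flag"] == "argmax"]
    return am.set_index("branch")["cosine"].astype(float)


# ---------------------------------------------------------------------------
# driver attribution


def driver_signature_probability(
    clonal_contributions: pd.Series | dict,
    driver_channel: str,
    signatures: pd.DataFrame,
) -> pd.Series:
    """Probability that each signature caused a driver mutation.

    Each clonal-class contribution is multiplied by the signature's weight
    on the driver's trinucleotide channel; probabilities are normalized to
    sum 1 and are invariant to rescaling all contributions.
    """
    contrib = pd.Series(clonal_contributions, dtype=float)
    if driver_channel not in CHANNELS:
        raise ValueError(f"unknown substitution channel {driver_channel!r}")
    S = signatures / signatures.sum(axis=0)
    raw = pd.Series(
        {s: contrib.get(s, 0.0) * float(S.loc[driver_channel, s])
         for s in contrib.index}
    )
    total = raw.sum()
    if total <= 0:
        raise ValueError(
            "driver context unexplained: all signature probabilities are zero"
        )
    return raw / total
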