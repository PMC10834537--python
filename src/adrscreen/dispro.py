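"""Disproportionality analysis of spontaneous-report (SRS) data.

Case/non-case analysis: for each (drug, event) pair, reports are
cross-classified by whether they mention the drug and whether they mention
the event (the distinct report is the counting unit). Three
disproportionality statistics are computed per pair —

    PRR = (a/(a+b)) / (c/(c+d))
    ROR = (a/b) / (c/d)
    IC  = log2( a·n / ((a+c)(a+b)) )

— each with a ranked false-discovery-rate decision at a configurable
threshold (default 0.05):

* PRR and ROR: one-sided Wald p-values on the log scale
  (se_logPRR = sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d)),
  se_logROR = sqrt(1/a + 1/b + 1/c + 1/d)), Benjamini–Hochberg adjusted.
* IC: the posterior probability P(IC ≤ 0 | data) under a
  Dirichlet(a+1, b+1, c+1, d+1) posterior on the four cell probabilities,
  estimated by Monte Carlo; the Bayesian FDR at rank i is the cumulative
  mean of the sorted posterior null probabilities.

Zero cells get the Haldane–Anscombe 0.5 correction for point estimates and
Wald variances (flagged ``corrected``); the IC posterior handles zeros
through its prior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

from .contingency import corrected_cells, dispro_stats_arrays, log_prr_se, log_ror_se
from .datasets import SrsDataset, VocabMappings

__all__ = [
    "ReportTable",
    "build_case_noncase",
    "Disproportionality",
    "DisproResults",
    "fdr_rank",
    "ic_posterior_null_prob",
    "validate_candidates",
]

logger = logging.getLogger(__name__)

_MIN_RECOMMENDED_DRAWS = 1000


@dataclass
class ReportTable:
    """Distinct-report counts for every observed (drug, event) pair.

    ``pairs`` has columns drug, event, a, b, c, d where a is the number of
    distinct reports mentioning both the drug and the event, b the reports
    with the drug but other events, c the reports with the event but other
    drugs and d the remainder; a+b+c+d = ``n_reports`` for every pair.
    """

    n_reports: int
    pairs: pd.DataFrame
    drug_margins: pd.Series
    event_margins: pd.Series


def build_case_noncase(srs: SrsDataset, mappings: VocabMappings) -> ReportTable:
    """Build the case/non-case table from raw SRS mentions.

    Drug names (possibly brands) are normalised to generics and raw event
    terms to preferred terms before counting; duplicate (report, drug,
    event) rows collapse. A report with k drugs and m events contributes to
    all k×m pairs but is counted once per pair.
    """
    frame = srs.reports
    if len(frame) == 0:
        return ReportTable(
            n_reports=0,
            pairs=pd.DataFrame(columns=["drug", "event", "a", "b", "c", "d"]),
            drug_margins=pd.Series(dtype=int),
            event_margins=pd.Series(dtype=int),
        )
    frame = frame.copy()
    frame["drug"] = mappings.map_drugs(frame["drug_name"])
    frame["event"] = mappings.map_terms(frame["event_term"])

    drug_mentions = frame[["report_id", "drug"]].drop_duplicates()
    event_mentions = frame[["report_id", "event"]].drop_duplicates()
    n_reports = int(frame["report_id"].nunique())
    drug_margins = drug_mentions.groupby("drug").size()
    event_margins = event_mentions.groupby("event").size()

    joint = (
        drug_mentions.merge(event_mentions, on="report_id")
        .groupby(["drug", "event"])
        .size()
        .rename("a")
        .reset_index()
    )
    joint["b"] = joint["drug"].map(drug_margins) - joint["a"]
    joint["c"] = joint["event"].map(event_margins) - joint["a"]
    joint["d"] = n_reports - joint["a"] - joint["b"] - joint["c"]
    joint = joint.sort_values(["drug", "event"], kind="stable").reset_index(drop=True)
    return ReportTable(
        n_reports=n_reports, pairs=joint, drug_margins=drug_margins, event_margins=event_margins
    )


def ic_posterior_null_prob(
    a, b, c, d, mc_draws: int = 10_000, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Monte-Carlo estimate of P(IC <= 0 | data) per table.

    Posterior: (p11, p10, p01, p00) ~ Dirichlet(a+1, b+1, c+1, d+1);
    IC <= 0 iff p11 <= (p11 + p10) * (p11 + p01).
    """
    if mc_draws < 1:
        raise ValueError("mc_draws must be >= 1")
    if mc_draws < _MIN_RECOMMENDED_DRAWS:
        logger.warning(
            "mc_draws=%d is below the recommended minimum of %d; "
            "posterior probabilities will be noisy",
            mc_draws,
            _MIN_RECOMMENDED_DRAWS,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells = np.column_stack(
        [np.asarray(a, float), np.asarray(b, float), np.asarray(c, float), np.asarray(d, float)]
    )
    n_pairs = cells.shape[0]
    out = np.empty(n_pairs)
    # chunk to bound memory at ~ chunk * mc_draws * 4 doubles
    chunk = max(1, int(2_000_000 // max(mc_draws, 1)))
    for start in range(0, n_pairs, chunk):
        block = cells[start : start + chunk]
        g = rng.standard_gamma(block[None, :, :] + 1.0, size=(mc_draws,) + block.shape)
        p = g / g.sum(axis=2, keepdims=True)
        null = p[:, :, 0] <= (p[:, :, 0] + p[:, :, 1]) * (p[:, :, 0] + p[:, :, 2])
        out[start : start + chunk] = null.mean(axis=0)
    return out


def _one_sided_wald_p(a, b, c, d, statistic: str) -> np.ndarray:
    af, bf, cf, df, _ = corrected_cells(a, b, c, d)
    if statistic == "prr":
        est = (af / (af + bf)) / (cf / (cf + df))
        se = log_prr_se(af, bf, cf, df)
    elif statistic == "ror":
        est = (af / bf) / (cf / df)
        se = log_ror_se(af, bf, cf, df)
    else:  # pragma: no cover - guarded by caller
        raise ValueError(statistic)
    z = np.log(est) / se
    return _stats.norm.sf(z)


def fdr_rank(
    pairs: pd.DataFrame,
    method: str,
    mc_draws: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Per-pair FDR values for one statistic, aligned with ``pairs`` rows.

    ``method`` is one of 'prr', 'ror' (Wald p-values, Benjamini–Hochberg) or
    'ic' (Monte-Carlo posterior null probabilities, cumulative-mean Bayesian
    FDR over the ranked pairs).
    """
    if len(pairs) < 1:
        raise ValueError("fdr_rank requires at least one pair")
    a = pairs["a"].to_numpy()
    b = pairs["b"].to_numpy()
    c = pairs["c"].to_numpy()
    d = pairs["d"].to_numpy()
    if method in ("prr", "ror"):
        p = _one_sided_wald_p(a, b, c, d, method)
        return multipletests(p, method="fdr_bh")[1]
    if method == "ic":
        post = ic_posterior_null_prob(a, b, c, d, mc_draws=mc_draws, seed=seed)
        return cumulative_mean_fdr(post)
    raise ValueError(f"unknown method {method!r}; expected 'prr', 'ror' or 'ic'")


def cumulative_mean_fdr(posterior_null: np.ndarray) -> np.ndarray:
    """Bayesian FDR: cumulative mean of the ascending-sorted null probabilities.

    Returns values aligned with the input order; the sequence is
    non-decreasing in rank by construction.
    """
    post = np.asarray(posterior_null, dtype=float)
    order = np.argsort(post, kind="stable")
    sorted_post = post[order]
    cum = np.cumsum(sorted_post) / np.arange(1, len(post) + 1)
    out = np.empty_like(cum)
    out[order] = cum
    return out


class Disproportionality:
    """Disproportionality model over a whole SRS pair universe.

    Statistics, marginals and FDR rankings are global by definition: they
    are computed over every observed pair, and candidate pairs are looked up
    afterwards with :meth:`DisproResults.annotate`.

    Parameters
    ----------
    table
        Output of :func:`build_case_noncase`.
    threshold
        FDR decision threshold (default 0.05).
    mc_draws
        Monte-Carlo draws for the IC posterior (default 10,000).
    """

    def __init__(self, table: ReportTable, *, threshold: float = 0.05, mc_draws: int = 10_000):
        self.table = table
        self.threshold = threshold
        self.mc_draws = mc_draws

    @classmethod
    def from_reports(
        cls, srs: SrsDataset, mappings: VocabMappings, **kwargs
    ) -> "Disproportionality":
        return cls(build_case_noncase(srs, mappings), **kwargs)

    def fit(self, seed: int | np.random.Generator | None = None) -> "DisproResults":
        pairs = self.table.pairs
        frame = pairs.copy()
        if len(frame) == 0:
            for col in (
                "prr",
                "ror",
                "ic",
                "corrected",
                "fdr_prr",
                "fdr_ror",
                "fdr_ic",
                "significant_any",
            ):
                frame[col] = pd.Series(dtype=float)
            return DisproResults(self, frame)
        a = frame["a"].to_numpy()
        b = frame["b"].to_numpy()
        c = frame["c"].to_numpy()
        d = frame["d"].to_numpy()
        prr, ror, ic, corrected = dispro_stats_arrays(a, b, c, d)
        frame["prr"] = prr
        frame["ror"] = ror
        frame["ic"] = ic
        frame["corrected"] = corrected
        frame["fdr_prr"] = fdr_rank(pairs, "prr")
        frame["fdr_ror"] = fdr_rank(pairs, "ror")
        frame["fdr_ic"] = fdr_rank(pairs, "ic", mc_draws=self.mc_draws, seed=seed)
        frame["significant_any"] = (
            frame[["fdr_prr", "fdr_ror", "fdr_ic"]].min(axis=1) < self.threshold
        )
        return DisproResults(self, frame)


class DisproResults:
    """Per-pair PRR/ROR/IC with FDR values and the any-of-three decision."""

    def __init__(self, model: Disproportionality, frame: pd.DataFrame):
        self.model = model
        self.frame = frame

    @property
    def significant_frame(self) -> pd.DataFrame:
        return self.frame.loc[self.frame["significant_any"]].reset_index(drop=True)

    def annotate(
        self, candidates: Iterable[tuple[str, str]], threshold: float | None = None
    ) -> pd.DataFrame:
        """Annotate candidate pairs with their disproportionality evidence.

        Candidates absent from the SRS (the pair never co-occurs) get
        ``in_srs=False`` and ``significant_any=False``, mirroring NA rows.
        """
        return validate_candidates(candidates, self, threshold=threshold)

    def summary(self) -> str:
        sig = self.significant_frame
        lines = [
            f"Disproportionality: reports={self.model.table.n_reports}, "
            f"pairs={len(self.frame)}, FDR threshold={self.model.threshold}",
            f"significant by any of PRR/ROR/IC: {len(sig)}",
        ]
        if len(sig):
            lines.append(
                sig[["drug", "event", "a", "prr", "ror", "ic", "fdr_prr", "fdr_ror", "fdr_ic"]]
                .to_string(index=False, float_format=lambda v: f"{v:.3g}")
            )
        return "\n".join(lines)


def validate_candidates(
    candidates: Iterable[tuple[str, str]],
    results: DisproResults,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Look up candidate (drug, term) pairs in fitted SRS results.

    Each candidate is annotated with its statistics and FDRs, or marked
    absent when it never co-occurs in the SRS. ``significant_any`` applies
    the any-of-the-three rule at ``threshold`` (defaulting to the model's).
    """
    threshold = results.model.threshold if threshold is None else threshold
    indexed = results.frame.set_index(["drug", "event"])
    rows = []
    for drug, term in candidates:
        key = (drug, term)
        if key in indexed.index:
            row = indexed.loc[key]
            rows.append(
                dict(
                    drug=drug,
                    term=term,
                    in_srs=True,
                    a=int(row["a"]),
                    prr=float(row["prr"]),
                    ror=float(row["ror"]),
                    ic=float(row["ic"]),
                    fdr_prr=float(row["fdr_prr"]),
                    fdr_ror=float(row["fdr_ror"]),
                    fdr_ic=float(row["fdr_ic"]),
                    significant_any=bool(
                        min(row["fdr_prr"], row["fdr_ror"], row["fdr_ic"]) < threshold
                    ),
                )
            )
        else:
            rows.append(
                dict(
                    drug=drug,
                    term=term,
                    in_srs=False,
                    a=0,
                    prr=np.nan,
                    ror=np.nan,
                    ic=np.nan,
                    fdr_prr=np.nan,
                    fdr_ror=np.nan,
                    fdr_ic=np.nan,
                    significant_any=False,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "drug",
            "term",
            "in_srs",
            "a",
            "prr",
            "ror",
            "ic",
            "fdr_prr",
            "fdr_ror",
            "fdr_ic",
            "significant_any",
        ],
    )
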