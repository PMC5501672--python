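"""Bis-MTS cross-linker span windows and per-conformer bridging predictions.

A bifunctional methanethiosulfonate reagent MnM with an n-methylene spacer
bridges two substituted cysteines when their Cβ–Cβ separation lies inside the
reagent's span window.  The maximal span follows the linear spacer model

    span_max(n) = 2.6 + 1.3 * n   [Å]

the unique line through the M3M (6.5 Å) and M8M (13 Å) anchors, which also
reproduces the M17M anchor (24.7 Å).  ``span_min = span_max / 2`` encodes
fold-back of the flexible chain: a reagent can still connect residues much
closer than its extended length, at reduced efficiency.

Classification of a distance series against a reagent:

* ``spontaneous_disulfide``  d ≤ 2.1 Å — direct S–S bond, no reagent needed;
* ``bridgeable_full``        span_min ≤ d ≤ span_max + slack_full;
* ``bridgeable_partial``     d below span_min (fold-back), or within
  ``slack_partial`` above the span;
* ``not_bridgeable``         otherwise.

The above-span slacks are *fluctuation-limited*: ``slack = min(tol,
k_sd·SD)`` of the distance series.  A pair whose mean separation exceeds the
extended reagent can only be caught transiently, so the allowance is earned
by the observed thermal fluctuation and capped by ``tol_full`` /
``tol_partial``; a static (zero-variance) distance gets strict windows, which
is why a rigid 25 Å pair is beyond even the longest reagent (M17M, 24.7 Å).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance_analysis import PairDistanceSeries

__all__ = [
    "Reagent",
    "DisulfideConstant",
    "CompatibilityCall",
    "reagent_span",
    "make_reagent",
    "default_panel",
    "classify_pair",
    "predict_pair",
    "concordance",
    "read_panel_tsv",
    "read_observations_tsv",
    "calls_to_frame",
    "CALLS",
    "BRIDGEABLE_CALLS",
]

SPAN_INTERCEPT = 2.6  # Å
SPAN_PER_METHYLENE = 1.3  # Å per CH2

CALLS = ("spontaneous_disulfide", "bridgeable_full", "bridgeable_partial", "not_bridgeable")
BRIDGEABLE_CALLS = frozenset({"spontaneous_disulfide", "bridgeable_full", "bridgeable_partial"})
# aggregate ranking across states: stronger evidence of cross-linking first
_RANK = {"bridgeable_full": 3, "spontaneous_disulfide": 2, "bridgeable_partial": 1, "not_bridgeable": 0}

OBSERVED_OUTCOMES = ("none", "partial", "full")


@dataclass(frozen=True)
class Reagent:
    """A cross-linking reagent with its Cβ–Cβ bridging window (Å)."""

    name: str
    n_methylene: int
    span_max: float
    span_min: float
    monofunctional: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.span_min < self.span_max:
            raise ValueError(f"{self.name}: require 0 < span_min < span_max")


@dataclass(frozen=True)
class DisulfideConstant:
    """Cβ–Cβ threshold for spontaneous disulfide formation (DMSO-only condition)."""

    d_ss: float = 2.1

    def __post_init__(self) -> None:
        if self.d_ss <= 0:
            raise ValueError("d_ss must be positive")


@dataclass(frozen=True)
class CompatibilityCall:
    pair_id: str
    state: str
    reagent: str
    call: str
    d_mean: float
    d_sd: float
    d_min: float
    n_frames: int


def reagent_span(n_methylene: int) -> float:
    """Maximal Cβ–Cβ bridging span (Å) of an n-methylene bis-MTS reagent."""
    if n_methylene < 1:
        raise ValueError("n_methylene must be >= 1")
    return SPAN_INTERCEPT + SPAN_PER_METHYLENE * n_methylene


def make_reagent(name: str, n_methylene: int, monofunctional: bool = False) -> Reagent:
    span = reagent_span(n_methylene)
    return Reagent(
        name=name,
        n_methylene=n_methylene,
        span_max=span,
        span_min=span / 2.0,
        monofunctional=monofunctional,
    )


def default_panel() -> list[Reagent]:
    """The MnM reagent panel: M1M, M2M, M3M, M5M, M8M, M17M."""
    return [make_reagent(f"M{n}M", n) for n in (1, 2, 3, 5, 8, 17)]


def classify_pair(
    series: PairDistanceSeries,
    reagent: Reagent,
    ss: DisulfideConstant = DisulfideConstant(),
    tol_full: float = 1.0,
    tol_partial: float = 3.0,
    k_sd: float = 2.0,
    use_min: bool = False,
) -> CompatibilityCall:
    """Predicted bridging outcome for one pair/state against one reagent.

    ``use_min`` classifies on the per-frame minimum distance instead of the
    mean (transient approaches can enable cross-linking).  The above-span
    slacks are ``min(tol, k_sd * SD)``; see the module docstring.
    """
    if reagent.monofunctional:
        raise ValueError(
            f"{reagent.name} is monofunctional: pore blockage, not a distance phenomenon"
        )
    d = series.min if use_min else series.mean
    sd = series.sd
    slack_full = min(tol_full, k_sd * sd)
    slack_partial = min(tol_partial, k_sd * sd)
    if d <= ss.d_ss:
        call = "spontaneous_disulfide"
    elif reagent.span_min <= d <= reagent.span_max + slack_full:
        call = "bridgeable_full"
    elif d < reagent.span_min or d <= reagent.span_max + slack_partial:
        call = "bridgeable_partial"
    else:
        call = "not_bridgeable"
    return CompatibilityCall(
        pair_id=series.pair.id,
        state=series.state,
        reagent=reagent.name,
        call=call,
        d_mean=series.mean,
        d_sd=sd,
        d_min=series.min,
        n_frames=series.n_frames,
    )


@dataclass
class PairPrediction:
    """Per-state and aggregate calls for one pair over a reagent panel."""

    pair_id: str
    per_state: dict  # state -> {reagent name -> CompatibilityCall}
    aggregate: dict  # reagent name -> (best call, tuple of supporting states)

    @property
    def bridgeable(self) -> bool:
        return any(call in BRIDGEABLE_CALLS for call, _ in self.aggregate.values())


def predict_pair(
    series_by_state: dict,
    panel: list[Reagent] | None = None,
    **classify_kwargs,
) -> PairPrediction:
    """Conformer-resolved bridging prediction.

    The aggregate call per reagent is the best call across states (a reagent
    cross-links whichever conformation puts the pair in range), annotated with
    the states supporting it.  Monofunctional reagents are excluded.
    """
    if not series_by_state:
        raise ValueError("need at least one state")
    panel = default_panel() if panel is None else panel
    panel = [r for r in panel if not r.monofunctional]
    pair_ids = {s.pair.id for s in series_by_state.values()}
    if len(pair_ids) != 1:
        raise ValueError(f"series must all describe one pair, got {sorted(pair_ids)}")
    per_state = {
        state: {r.name: classify_pair(s, r, **classify_kwargs) for r in panel}
        for state, s in series_by_state.items()
    }
    aggregate = {}
    for r in panel:
        best = max(_RANK[per_state[state][r.name].call] for state in per_state)
        call = next(c for c, k in _RANK.items() if k == best)
        support = tuple(
            sorted(state for state in per_state if _RANK[per_state[state][r.name].call] == best)
        )
        aggregate[r.name] = (call, support if call in BRIDGEABLE_CALLS else ())
    return PairPrediction(pair_id=pair_ids.pop(), per_state=per_state, aggregate=aggregate)


def concordance(predictions: list[PairPrediction], observations: pd.DataFrame) -> dict:
    """Reconcile predicted bridging against experimental cross-linking outcomes.

    A pair is concordant when *any predicted bridgeable* matches *any observed
    cross-linking* (outcome ``partial`` or ``full``) over its tested reagents.
    Also reports a per-reagent confusion table at the none-vs-any level.
    Unmatched observation rows are reported, never silently dropped.
    """
    obs = observations.copy()
    bad = set(obs["outcome"]) - set(OBSERVED_OUTCOMES)
    if bad:
        raise ValueError(f"unknown observed outcomes {sorted(bad)}; allowed: {OBSERVED_OUTCOMES}")
    dup = obs.duplicated(subset=["pair_id", "reagent"])
    if dup.any():
        rows = obs.loc[dup, ["pair_id", "reagent"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate observation rows for {rows}")

    pred_by_pair = {p.pair_id: p for p in predictions}
    matched = obs[obs["pair_id"].isin(pred_by_pair)]
    unmatched = obs[~obs["pair_id"].isin(pred_by_pair)]

    verdicts = []
    for pair_id, rows in matched.groupby("pair_id", sort=True):
        pred = pred_by_pair[pair_id]
        # restrict the prediction to the reagents actually tested on this pair
        tested = [r for r in rows["reagent"] if r in pred.aggregate]
        predicted = any(pred.aggregate[r][0] in BRIDGEABLE_CALLS for r in tested)
        observed = any(o in ("partial", "full") for o in rows["outcome"])
        verdicts.append({"pair_id": pair_id, "predicted": predicted, "observed": observed,
                         "concordant": predicted == observed})
    verdict_table = pd.DataFrame(verdicts, columns=["pair_id", "predicted", "observed", "concordant"])

    confusion = {}
    for reagent, rows in matched.groupby("reagent", sort=True):
        tp = fp = fn = tn = 0
        for _, row in rows.iterrows():
            pred = pred_by_pair[row["pair_id"]]
            if reagent not in pred.aggregate:
                continue
            p = pred.aggregate[reagent][0] in BRIDGEABLE_CALLS
            o = row["outcome"] in ("partial", "full")
            tp += p and o
            fp += p and not o
            fn += (not p) and o
            tn += (not p) and (not o)
        confusion[reagent] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}

    n_tested = len(verdict_table)
    n_concordant = int(verdict_table["concordant"].sum()) if n_tested else 0
    return {
        "per_pair": verdict_table,
        "n_tested": n_tested,
        "n_concordant": n_concordant,
        "concordance": (n_concordant / n_tested) if n_tested else float("nan"),
        "per_reagent_confusion": confusion,
        "unmatched_observations": unmatched.reset_index(drop=True),
    }


def calls_to_frame(predictions: list[PairPrediction]) -> pd.DataFrame:
    """Flatten predictions into a tidy per-(pair, state, reagent) call matrix."""
    rows = []
    for p in predictions:
        for state, by_reagent in p.per_state.items():
            for call in by_reagent.values():
                rows.append(
                    {
                        "pair": call.pair_id,
                        "state": state,
                        "reagent": call.reagent,
                        "call": call.call,
                        "d_mean": call.d_mean,
                        "d_sd": call.d_sd,
                    }
                )
        for reagent, (call, support) in p.aggregate.items():
            rows.append(
                {
                    "pair": p.pair_id,
                    "state": "aggregate" + (f"({','.join(support)})" if support else ""),
                    "reagent": reagent,
                    "call": call,
                    "d_mean": np.nan,
                    "d_sd": np.nan,
                }
            )
    return pd.DataFrame(rows)


def read_panel_tsv(path) -> list[Reagent]:
    """Reagent panel TSV: name, n_methylene[, span_max, span_min, monofunctional]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        n = int(row["n_methylene"])
        span_max = float(row["span_max"]) if "span_max" in df and pd.notna(row.get("span_max")) else reagent_span(n)
        span_min = float(row["span_min"]) if "span_min" in df and pd.notna(row.get("span_min")) else span_max / 2.0
        mono = bool(row["monofunctional"]) if "monofunctional" in df and pd.notna(row.get("monofunctional")) else False
        out.append(Reagent(name=str(row["name"]), n_methylene=n, span_max=span_max,
                           span_min=span_min, monofunctional=mono))
    return out


def read_observations_tsv(path) -> pd.DataFrame:
    """Observation table TSV: pair_id, reagent, outcome in {none, partial, full}."""
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "reagent": str, "outcome": str})
    missing = {"pair_id", "reagent", "outcome"} - set(df.columns)
    if missing:
        raise ValueError(f"observation table missing columns {sorted(missing)}")
    return df
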