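"""Forward selection of MVMR exposures by conditional instrument strength.

Fitting many genetically correlated exposures in one multivariable MR model
usually collapses the conditional F-statistics below the conventional
threshold of 10, making direct effects uninterpretable. The algorithm here
selects the largest exposure set that keeps every conditional F above the
threshold:

1. evaluate all C(K,2) two-exposure MVMR models and score each pair by its
   mean conditional F penalized by the within-pair imbalance — balanced
   pairs can absorb the attenuation caused by later additions, unbalanced
   pairs cannot;
2. seed the model with the highest-scoring feasible pair;
3. repeatedly try each remaining exposure; a candidate is feasible when the
   augmented model keeps every conditional F (including the candidate's
   own) at or above the threshold; among feasible candidates pick the one
   maximizing the minimum conditional F, tie-breaking by mean conditional F
   then by name;
4. stop when no candidate is feasible. Candidates that fail are excluded
   permanently (strict forward selection, no backtracking).

Every model evaluation is recorded in a :class:`SelectionTrace` so the path
to the final model can be audited.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import MRSelectError
from .mvmr import ConditionalStrength, conditional_f
from .summary_data import AssociationTable, assemble_mvmr_set

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).eps


@dataclass
class PairScore:
    """Conditional strength of a two-exposure MVMR model, scored for seeding."""

    exposure_a: str
    exposure_b: str
    f_a: float
    f_b: float
    mean_f: float
    delta_f: float
    score: float
    feasible: bool
    reason: str = ""


def score_pair(
    f_a: float, f_b: float, threshold: float = 10.0, raw_inverse: bool = False
) -> PairScore:
    """Score a pair of conditional F-statistics for seed selection.

    The default score is mean_f / (1 + |f_a - f_b|): a bounded version of
    weighting the pair mean by the inverse absolute difference, finite for
    perfectly balanced pairs while preserving the ordering that a balanced
    pair beats an unbalanced pair of equal mean. ``raw_inverse`` switches to
    mean_f / max(|f_a - f_b|, machine epsilon).
    """
    if f_a < 0 or f_b < 0:
        raise ValueError("conditional F-statistics must be non-negative")
    mean_f = 0.5 * (f_a + f_b)
    delta_f = abs(f_a - f_b)
    if raw_inverse:
        score = mean_f / max(delta_f, _EPS)
    else:
        score = mean_f / (1.0 + delta_f)
    return PairScore(
        exposure_a="",
        exposure_b="",
        f_a=float(f_a),
        f_b=float(f_b),
        mean_f=float(mean_f),
        delta_f=float(delta_f),
        score=float(score),
        feasible=bool(min(f_a, f_b) >= threshold),
    )


@dataclass
class SelectionStep:
    """One audited event of the forward-selection run."""

    action: str  # seed_pair | add | reject | stop
    candidate: str | tuple[str, str] | None
    conditional_f_after: dict[str, float]
    reason: str = ""


@dataclass
class SelectionTrace:
    """Step-by-step record and final model of a forward-selection run."""

    steps: list[SelectionStep] = field(default_factory=list)
    final_model: list[str] = field(default_factory=list)
    final_strength: ConditionalStrength | None = None

    def to_text(self) -> str:
        lines = []
        for i, s in enumerate(self.steps, 1):
            fs = ", ".join(f"{k}={v:.2f}" for k, v in s.conditional_f_after.items())
            lines.append(f"step {i}: {s.action} {s.candidate!r} [{fs}] {s.reason}")
        lines.append(f"final model: {self.final_model or '(empty)'}")
        return "\n".join(lines)


@dataclass
class PairEnumeration:
    """All pairwise models: ranked scores plus the K x K conditional-F matrix."""

    scores: list[PairScore]
    f_matrix: pd.DataFrame  # f_matrix.loc[partner, exposure] = F(exposure | partner)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "exposure_a": s.exposure_a,
                    "exposure_b": s.exposure_b,
                    "f_a": s.f_a,
                    "f_b": s.f_b,
                    "mean_f": s.mean_f,
                    "delta_f": s.delta_f,
                    "score": s.score,
                    "feasible": s.feasible,
                    "reason": s.reason,
                }
                for s in self.scores
            ]
        )


def _fit_pair(
    table_a: AssociationTable,
    table_b: AssociationTable,
    outcome: AssociationTable,
    threshold: float,
    assemble_kwargs: dict,
) -> tuple[float, float]:
    hset = assemble_mvmr_set([table_a, table_b], outcome, **assemble_kwargs)
    strength = conditional_f(hset, threshold=threshold)
    return strength.conditional_f[0], strength.conditional_f[1]


def enumerate_pairs(
    exposures: Sequence[AssociationTable],
    outcome: AssociationTable,
    threshold: float = 10.0,
    raw_inverse: bool = False,
    **assemble_kwargs,
) -> PairEnumeration:
    """Fit all two-exposure MVMR models and rank the pairs by score.

    Pairs that cannot be fit (too few shared instruments, collinearity) are
    returned infeasible with the failure reason rather than raising. The
    ``f_matrix`` holds the conditional F of the column exposure when paired
    with the row exposure — the heat-map layout used to visualize pairwise
    conditional strength.
    """
    if len(exposures) < 2:
        raise MRSelectError("pair enumeration requires at least 2 exposures")
    names = [t.trait_name for t in exposures]
    f_matrix = pd.DataFrame(np.nan, index=names, columns=names)
    scores: list[PairScore] = []
    for (i, ta), (j, tb) in itertools.combinations(enumerate(exposures), 2):
        try:
            f_a, f_b = _fit_pair(ta, tb, outcome, threshold, assemble_kwargs)
        except MRSelectError as exc:
            ps = PairScore(names[i], names[j], np.nan, np.nan, np.nan, np.nan,
                           -np.inf, feasible=False, reason=str(exc))
            scores.append(ps)
            continue
        ps = score_pair(f_a, f_b, threshold, raw_inverse)
        ps.exposure_a, ps.exposure_b = names[i], names[j]
        scores.append(ps)
        f_matrix.loc[names[j], names[i]] = f_a
        f_matrix.loc[names[i], names[j]] = f_b
    scores.sort(key=lambda s: (-s.score, s.exposure_a, s.exposure_b))
    return PairEnumeration(scores, f_matrix)


def forward_select(
    exposures: Sequence[AssociationTable],
    outcome: AssociationTable,
    threshold: float = 10.0,
    raw_inverse: bool = False,
    **assemble_kwargs,
) -> SelectionTrace:
    """Forward-select the largest exposure set with all conditional F >= threshold.

    Returns a :class:`SelectionTrace`; when no pair is feasible the final
    model is empty and the trace records the stop reason instead of raising.
    """
    by_name = {t.trait_name: t for t in exposures}
    if len(by_name) != len(exposures):
        raise MRSelectError("exposure trait names must be unique")
    trace = SelectionTrace()

    pairs = enumerate_pairs(
        exposures, outcome, threshold, raw_inverse, **assemble_kwargs
    )
    seed = next((p for p in pairs.scores if p.feasible), None)
    if seed is None:
        trace.steps.append(
            SelectionStep("stop", None, {}, "no feasible seed pair")
        )
        return trace

    included = [seed.exposure_a, seed.exposure_b]
    current_f = {seed.exposure_a: seed.f_a, seed.exposure_b: seed.f_b}
    trace.steps.append(
        SelectionStep(
            "seed_pair", (seed.exposure_a, seed.exposure_b), dict(current_f),
            f"highest-scoring feasible pair (score={seed.score:.3f})",
        )
    )
    remaining = [n for n in by_name if n not in included]

    while remaining:
        candidates: list[tuple[str, ConditionalStrength]] = []
        excluded: list[str] = []
        for name in remaining:
            model = included + [name]
            try:
                hset = assemble_mvmr_set(
                    [by_name[m] for m in model], outcome, **assemble_kwargs
                )
                strength = conditional_f(hset, threshold=threshold)
            except MRSelectError as exc:
                trace.steps.append(SelectionStep("reject", name, {}, str(exc)))
                excluded.append(name)
                continue
            fs = dict(zip(model, strength.conditional_f))
            if strength.all_pass:
                candidates.append((name, strength))
            else:
                weak = [m for m, f in fs.items() if f < threshold]
                trace.steps.append(
                    SelectionStep(
                        "reject", name, fs,
                        "conditional F below threshold for " + ", ".join(
                            f"{m} (F={fs[m]:.2f})" for m in weak
                        ),
                    )
                )
                excluded.append(name)
        if not candidates:
            trace.steps.append(
                SelectionStep(
                    "stop", None, dict(current_f),
                    "no remaining exposure keeps all conditional F >= threshold",
                )
            )
            break
        # most robust addition: maximize the worst conditional F,
        # tie-break by mean conditional F, then by name
        def key(item: tuple[str, ConditionalStrength]):
            _, s = item
            return (-np.min(s.conditional_f), -np.mean(s.conditional_f), item[0])

        chosen_name, chosen_strength = min(candidates, key=key)
        included.append(chosen_name)
        current_f = dict(zip(chosen_strength.exposure_names, chosen_strength.conditional_f))
        trace.steps.append(
            SelectionStep(
                "add", chosen_name, dict(current_f),
                f"maximizes minimum conditional F ({np.min(chosen_strength.conditional_f):.2f})",
            )
        )
        remaining = [n for n in remaining if n != chosen_name and n not in excluded]
    else:
        trace.steps.append(
            SelectionStep("stop", None, dict(current_f), "no exposures remaining")
        )

    trace.final_model = included
    trace.final_strength = ConditionalStrength(
        included, np.array([current_f[n] for n in included]), threshold
    )
    return trace
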