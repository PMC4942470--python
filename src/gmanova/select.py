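"""Forward stepwise model selection and the I-X selected-model taxonomy.

The selector mirrors classic forward-stepwise-with-removal at significance
thresholds for entry and stay (default 0.05 each): at every iteration the
candidate whose partial F (in the enlarged model) has the smallest p-value
enters if p < p_enter; after each entry, included variables whose partial F
p-value exceeds p_stay are removed, worst first.  The intercept is always
included.  Ties are broken by canonical column order and a repeated-state
guard terminates enter/remove cycles.

Selected models over the eight two-locus candidates (roles w1, v1, w2, v2,
ww, wv, vw, vv — dummy or mean-corrected flavor) are classified into ten
types by membership of the five main candidates w1, w2, ww, v1, v2, evaluated
with precedence I through X (first match wins):

  I    w1, w2, ww, v1, v2 all selected
  II   w1, w2, ww, v1 selected (v2 not)
  III  w1, w2, ww, v2 selected (v1 not)
  IV   w1, w2, ww selected (neither v)
  V    w1, w2 selected, ww not
  VI   w1, ww selected, w2 not
  VII  w2, ww selected, w1 not
  VIII ww selected, neither w
  IX   exactly one of w1/w2 selected, ww not
  X    none of w1, w2, ww selected
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import coding
from .fit import ModelSpec, build_design
from .simulate import SimulationConfig, default_study_config, replicate_seeds, simulate_dataset

logger = logging.getLogger(__name__)

MODEL_TYPES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")

#: canonical role names of the eight two-locus candidate variables, in the
#: design block order A1, D1, A2, D2, AA, AD, DA, DD
CANDIDATE_ROLES = ("w1", "v1", "w2", "v2", "ww", "wv", "vw", "vv")


@dataclass
class StepwiseResult:
    """Outcome of a stepwise run: selected labels and the per-step log."""

    selected: tuple[str, ...]
    log: list[dict] = field(default_factory=list)


def forward_stepwise(
    X: np.ndarray,
    y: np.ndarray,
    labels: Sequence[str] | None = None,
    p_enter: float = 0.05,
    p_stay: float = 0.05,
) -> StepwiseResult:
    """Forward stepwise selection with removal over candidate columns of X.

    ``X`` holds the candidate columns only (no intercept column); the
    intercept is implicit and always included.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need n > number of candidates + 1")
    labels = list(labels) if labels is not None else [f"x{i}" for i in range(k)]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    G = Xc.T @ Xc
    c = Xc.T @ yc
    Syy = float(yc @ yc)

    def sse(S: list[int]) -> float:
        if not S:
            return Syy
        idx = np.asarray(S)
        sub = G[np.ix_(idx, idx)]
        try:
            b = np.linalg.solve(sub, c[idx])
        except np.linalg.LinAlgError:
            return np.nan
        return max(Syy - float(c[idx] @ b), 0.0)

    model: list[int] = []
    log: list[dict] = []
    seen: set[frozenset] = set()
    sse_cur = Syy
    while True:
        state = frozenset(model)
        if state in seen:
            break
        seen.add(state)
        # --- entry step
        best = None
        for j in range(k):
            if j in model:
                continue
            s2 = sse(model + [j])
            if not np.isfinite(s2):
                logger.warning("candidate %s skipped: collinear with current model", labels[j])
                continue
            df2 = n - len(model) - 2
            F = (sse_cur - s2) / (s2 / df2) if s2 > 0 else np.inf
            p = float(stats.f.sf(F, 1, df2))
            if best is None or p < best[0]:
                best = (p, j, F, s2)
        entered = False
        if best is not None and best[0] < p_enter:
            p, j, F, s2 = best
            model.append(j)
            sse_cur = s2
            log.append({"action": "enter", "variable": labels[j], "F": F, "p": p})
            entered = True
        # --- removal steps
        while model:
            worst = None
            df2 = n - len(model) - 1
            for j in model:
                rest = [i for i in model if i != j]
                s_red = sse(rest)
                F = (s_red - sse_cur) / (sse_cur / df2) if sse_cur > 0 else np.inf
                p = float(stats.f.sf(F, 1, df2))
                if worst is None or p > worst[0]:
                    worst = (p, j, F)
            if worst is not None and worst[0] > p_stay:
                p, j, F = worst
                model.remove(j)
                sse_cur = sse(model)
                log.append({"action": "remove", "variable": labels[j], "F": F, "p": p})
            else:
                break
        if not entered:
            break
    selected = tuple(labels[j] for j in sorted(model))
    return StepwiseResult(selected=selected, log=log)


def classify_model(selected: Sequence[str]) -> str:
    """Classify a selected candidate set into the ten model types I-X."""
    s = set(selected)
    unknown = s - set(CANDIDATE_ROLES)
    if unknown:
        raise ValueError(f"unknown candidate names: {sorted(unknown)}")
    w1, w2, ww = "w1" in s, "w2" in s, "ww" in s
    v1, v2 = "v1" in s, "v2" in s
    if w1 and w2 and ww:
        if v1 and v2:
            return "I"
        if v1:
            return "II"
        if v2:
            return "III"
        return "IV"
    if w1 and w2:
        return "V"
    if w1 and ww:
        return "VI"
    if w2 and ww:
        return "VII"
    if ww:
        return "VIII"
    if w1 or w2:
        return "IX"
    return "X"


def run_selection_experiment(
    n: int,
    replicates: int,
    seed,
    coding_flavor: str = coding.GMA,
    config: SimulationConfig | None = None,
    p_enter: float = 0.05,
    p_stay: float = 0.05,
) -> pd.Series:
    """Replicated simulate → code → stepwise → classify study.

    Returns the count of replicates falling in each model type I-X (summing
    to ``replicates``).  Candidate columns are the eight two-locus code
    variables in either the dummy (GLM) or mean-corrected (GMA) flavor, the
    latter built with allele frequencies estimated from each replicate.
    """
    counts = dict.fromkeys(MODEL_TYPES, 0)
    if replicates <= 0:
        return pd.Series(counts, name="count")
    base = config if config is not None else default_study_config(n=n)
    cfg = SimulationConfig(
        loci=base.loci, params=base.params, V_eps=base.V_eps, H2=base.H2, n=n,
        hwd=base.hwd, joint_probs=base.joint_probs,
    )
    spec = ModelSpec(coding=coding_flavor, n_loci=2)
    for child in replicate_seeds(seed, replicates):
        ds = simulate_dataset(cfg, seed=child)
        design = build_design(ds, spec)
        X = design.X[:, 1:]
        if X.shape[1] != len(CANDIDATE_ROLES):
            raise ValueError("the I-X taxonomy is defined for two biallelic loci")
        res = forward_stepwise(
            X, ds.phenotype, labels=CANDIDATE_ROLES, p_enter=p_enter, p_stay=p_stay
        )
        counts[classify_model(res.selected)] += 1
    return pd.Series(counts, name="count")
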