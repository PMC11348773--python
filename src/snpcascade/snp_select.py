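"""Iterative discovery of minimal diagnostic SNP sets.

Starting from a full-pool DAPC, loci are ranked by their summed
discriminant contributions ("LD values").  The top batch seeds a candidate
panel; DAPC is refit on the candidate panel and a separation criterion is
evaluated for the target group — every target sample must be assigned to
the target with posterior at least tau, and no non-target sample may be
pulled into the target.  While the criterion fails, the next batch of
ranked loci is tried: batches that raise the separation metric by at least
``epsilon`` are retained, unhelpful batches are discarded and never
retried for the same target.  Repeating the procedure for every group and
taking the union of the per-group sets yields the diagnostic panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dapc import fit_dapc, ld_values, predict_dapc


@dataclass
class SelectionState:
    """Per-target log of the iterative selection procedure."""

    target: str
    pool: list[str]
    selected: list[str]
    tau: float
    epsilon: float
    converged: bool
    metric: float
    rounds: list[dict] = field(default_factory=list)  # per-round log entries


def separation_criterion(
    posteriors: np.ndarray,
    classes: Sequence[str],
    labels: Sequence[str],
    target: str,
    tau: float = 0.95,
) -> tuple[bool, float]:
    """Is the target group cleanly separated from everything else?

    TRUE iff every target sample has posterior(target) >= tau *and* no
    non-target sample is assigned (argmax) to the target.  The metric is
    the minimum target-posterior over target samples: 1.0 means every
    target sample sits unambiguously in its own cluster.
    """
    labels = np.asarray([str(l) for l in labels])
    classes = [str(c) for c in classes]
    if target not in classes or not (labels == target).any():
        raise ValueError(f"empty or unknown target group {target!r}")
    t = classes.index(target)
    is_target = labels == target
    assigned = np.argmax(posteriors, axis=1) == t
    metric = float(posteriors[is_target, t].min())
    ok = bool(
        metric >= tau and np.all(assigned[is_target]) and not np.any(assigned[~is_target])
    )
    return ok, metric


def _evaluate(gm, labels, loci, target, tau, n_pca):
    sub = gm.subset(loci=loci)
    model = fit_dapc(sub, labels, n_pca=n_pca)
    post, _ = predict_dapc(model, sub)
    return separation_criterion(post, model.classes, labels, target, tau)


def iterative_select(
    gm,
    labels: Sequence[str],
    target: str,
    batch_size: int = 25,
    tau: float = 0.95,
    max_rounds: int = 40,
    epsilon: float = 0.01,
    n_pca: int | None = None,
) -> tuple[list[str], SelectionState]:
    """Grow a minimal locus set that separates ``target`` from the rest.

    Round 1 takes the top ``batch_size`` loci by LD value from a DAPC on
    the full pool.  Each later round appends the next ranked batch, keeps
    it if the separation metric improves by >= ``epsilon``, and otherwise
    discards it permanently.  Stops when the criterion holds or after
    ``max_rounds`` (then the best state is returned, flagged
    ``converged=False``).
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if gm.n_loci == 0:
        raise ValueError("empty locus pool")
    labels = [str(l) for l in labels]

    full_model = fit_dapc(gm, labels, n_pca=n_pca)
    ranking = [gm.locus_ids[j] for j in np.argsort(ld_values(full_model))[::-1]]

    selected = ranking[:batch_size]
    remaining = ranking[batch_size:]
    ok, metric = _evaluate(gm, labels, selected, target, tau, n_pca)
    state = SelectionState(
        target=str(target), pool=list(gm.locus_ids), selected=list(selected),
        tau=tau, epsilon=epsilon, converged=ok, metric=metric,
        rounds=[{"round": 1, "added": list(selected), "kept": True,
                 "metric": metric, "separated": ok}],
    )
    rounds = 1
    while not ok and remaining and rounds < max_rounds:
        rounds += 1
        batch = remaining[:batch_size]
        remaining = remaining[batch_size:]
        trial = selected + batch
        new_ok, new_metric = _evaluate(gm, labels, trial, target, tau, n_pca)
        useful = new_ok or (new_metric - metric >= epsilon)
        if useful:
            selected = trial
            metric = new_metric
            ok = new_ok
        state.rounds.append(
            {"round": rounds, "added": list(batch), "kept": useful,
             "metric": new_metric, "separated": new_ok}
        )
    state.selected = list(selected)
    state.converged = ok
    state.metric = metric
    return selected, state


def select_all_groups(
    gm,
    labels: Sequence[str],
    order: Sequence[str] | None = None,
    **params,
) -> tuple[dict[str, list[str]], list[str]]:
    """Run :func:`iterative_select` for every group; return the union panel.

    ``order`` fixes the sequence in which groups are peeled off (broad
    clusters first, by convention); it must cover all groups and defaults
    to sorted label order.
    """
    labels = [str(l) for l in labels]
    groups = sorted(set(labels))
    if order is None:
        order = groups
    if sorted(set(order)) != groups:
        raise ValueError("order must cover exactly the observed groups")
    per_group: dict[str, list[str]] = {}
    panel: list[str] = []
    seen = set()
    for target in order:
        sel, _ = iterative_select(gm, labels, target, **params)
        per_group[target] = sel
        for l in sel:
            if l not in seen:
                seen.add(l)
                panel.append(l)
    return per_group, panel
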