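"""Class-frequency pharmacophore enrichment with a hypergeometric test.

For every descriptor key observed in a labelled compound library we
compute

* ``pa`` — the key's frequency within the active class,
* ``pi`` — its frequency within the inactive class,
* ``pr`` — a one-sided hypergeometric tail probability for the observed
  active/inactive imbalance,

and apply the decision rule: a key is a *presence* pharmacophore if
``pr <= alpha`` and ``pa > pi``, an *absence* pharmacophore if
``pr <= alpha`` and ``pi > pa``, and *neutral* otherwise.

Two frequency modes are supported.  In ``occurrence`` mode (the default)
the urn consists of descriptor *instances*: ``pa`` is the share of the
active class's descriptor instances carried by the key, and the test draws
the active class's instance total from the pooled instance population.  In
``compound`` mode the urn consists of compounds and a key either is or is
not present in each.  No multiplicity correction is applied by default; a
Benjamini–Hochberg option is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .chem import ALL_FAMILIES, DescriptorKey, DescriptorProfile, Molecule, profiles_for

PRESENCE = "presence"
ABSENCE = "absence"
NEUTRAL = "neutral"

FrequencyMode = Literal["occurrence", "compound"]


@dataclass(frozen=True)
class EnrichmentRecord:
    """One descriptor's class statistics and pharmacophore label."""

    key: DescriptorKey
    pa: float
    pi: float
    pr: float
    label: str
    k_active: int
    k_inactive: int
    n_active_total: int
    n_inactive_total: int


def hypergeometric_pr(
    k_active: int,
    total_key: int,
    n_active: int,
    n_total: int,
    direction: Literal["enriched", "depleted"] = "enriched",
) -> float:
    """One-sided hypergeometric tail probability.

    ``n_active`` items are drawn without replacement from ``n_total`` items
    of which ``total_key`` carry the key; ``k_active`` of the draws carry
    it.  ``enriched`` returns P(X >= k_active), ``depleted`` P(X <= k_active).
    Computed from log survival/cumulative functions for stability; the
    result lies in (0, 1].
    """
    if not (0 <= total_key <= n_total and 0 <= n_active <= n_total):
        raise ValueError(
            f"inconsistent counts: total_key={total_key}, n_active={n_active}, "
            f"n_total={n_total}"
        )
    lo = max(0, total_key + n_active - n_total)
    hi = min(total_key, n_active)
    if not (lo <= k_active <= hi):
        raise ValueError(
            f"k_active={k_active} outside support [{lo}, {hi}] for "
            f"(total_key={total_key}, n_active={n_active}, n_total={n_total})"
        )
    if direction == "enriched":
        if k_active == lo:
            return 1.0
        xs = np.arange(k_active, hi + 1)
    elif direction == "depleted":
        if k_active == hi:
            return 1.0
        xs = np.arange(lo, k_active + 1)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    logp = logsumexp(_log_pmf(xs, total_key, n_active, n_total))
    p = float(np.exp(logp))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def _log_binom(a, b):
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _log_pmf(x, total_key, n_active, n_total):
    """Hypergeometric log pmf over the support, via log-gamma."""
    return (
        _log_binom(total_key, x)
        + _log_binom(n_total - total_key, n_active - x)
        - _log_binom(n_total, n_active)
    )


def class_frequencies(
    profiles: Sequence[DescriptorProfile],
    labels: Sequence[int],
    mode: FrequencyMode = "occurrence",
) -> pd.DataFrame:
    """Per-key class frequencies and counts.

    Returns a DataFrame indexed by :class:`DescriptorKey` with columns
    ``pa``, ``pi``, ``k_active``, ``k_inactive``, ``n_active_total``,
    ``n_inactive_total``.
    """
    if len(profiles) != len(labels):
        raise ValueError("profiles and labels must have equal length")
    labels = [int(l) for l in labels]
    if set(labels) - {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    for cls, name in ((1, "active"), (0, "inactive")):
        if cls not in labels:
            raise ValueError(f"empty {name} class")

    keys: dict[DescriptorKey, list[int]] = {}
    for prof, lab in zip(profiles, labels):
        for key, count in prof.counts.items():
            row = keys.setdefault(key, [0, 0])
            if mode == "occurrence":
                row[lab] += count
            elif mode == "compound":
                row[lab] += 1
            else:
                raise ValueError(f"unknown frequency mode {mode!r}")

    if mode == "occurrence":
        n_active_total = sum(p.total for p, l in zip(profiles, labels) if l == 1)
        n_inactive_total = sum(p.total for p, l in zip(profiles, labels) if l == 0)
    else:
        n_active_total = sum(labels)
        n_inactive_total = len(labels) - n_active_total

    records = []
    for key, (k_in, k_act) in keys.items():
        records.append(
            {
                "key": key,
                "pa": k_act / n_active_total,
                "pi": k_in / n_inactive_total,
                "k_active": k_act,
                "k_inactive": k_in,
                "n_active_total": n_active_total,
                "n_inactive_total": n_inactive_total,
            }
        )
    df = pd.DataFrame.from_records(records).set_index("key")
    order = sorted(range(len(df)), key=lambda i: df.index[i].sort_key)
    return df.iloc[order]


def classify_pharmacophores(
    freqs: pd.DataFrame,
    alpha: float = 0.05,
    adjust: Literal["none", "bh"] = "none",
) -> list[EnrichmentRecord]:
    """Apply the directional hypergeometric decision rule to each key.

    The test direction follows the sign of ``pa - pi``; ties are neutral
    with ``pr`` reported as 1.  With ``adjust="bh"`` the labels are decided
    on Benjamini–Hochberg adjusted tail probabilities instead (the raw
    ``pr`` is still reported).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    raw = []
    for key, row in freqs.iterrows():
        k_act, k_in = int(row["k_active"]), int(row["k_inactive"])
        n_act, n_in = int(row["n_active_total"]), int(row["n_inactive_total"])
        total_key = k_act + k_in
        n_total = n_act + n_in
        pa, pi = float(row["pa"]), float(row["pi"])
        if pa > pi:
            pr = hypergeometric_pr(k_act, total_key, n_act, n_total, "enriched")
        elif pi > pa:
            pr = hypergeometric_pr(k_act, total_key, n_act, n_total, "depleted")
        else:
            pr = 1.0
        raw.append((key, pa, pi, pr, k_act, k_in, n_act, n_in))

    if adjust == "bh":
        prs = np.array([r[3] for r in raw])
        decide = np.empty_like(prs)
        order = np.argsort(prs)
        m = len(prs)
        adj = prs[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        decide[order] = np.minimum(adj, 1.0)
    elif adjust == "none":
        decide = np.array([r[3] for r in raw])
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    out = []
    for (key, pa, pi, pr, k_act, k_in, n_act, n_in), p_dec in zip(raw, decide):
        if p_dec <= alpha and pa > pi:
            label = PRESENCE
        elif p_dec <= alpha and pi > pa:
            label = ABSENCE
        else:
            label = NEUTRAL
        out.append(
            EnrichmentRecord(key, pa, pi, pr, label, k_act, k_in, n_act, n_in)
        )
    return out


def screen_library(
    molecules: Sequence[Molecule],
    labels: Sequence[int],
    max_length: int = 5,
    families=ALL_FAMILIES,
    mode: FrequencyMode = "occurrence",
    alpha: float = 0.05,
    adjust: Literal["none", "bh"] = "none",
) -> pd.DataFrame:
    """End-to-end screen: enumerate descriptors, test every key, label it.

    Returns a DataFrame with one row per distinct key, sorted by ``pr``,
    with columns ``sd1, ld, sd2, bd, pa, pi, pr, label, k_active,
    k_inactive``.
    """
    profiles = profiles_for(molecules, max_length=max_length, families=families)
    freqs = class_frequencies(profiles, labels, mode=mode)
    records = classify_pharmacophores(freqs, alpha=alpha, adjust=adjust)
    rows = []
    for rec in records:
        sd1, ld, sd2, bd = rec.key.as_tuple()
        rows.append(
            {
                "sd1": sd1,
                "ld": ld,
                "sd2": sd2,
                "bd": bd,
                "pa": rec.pa,
                "pi": rec.pi,
                "pr": rec.pr,
                "label": rec.label,
                "k_active": rec.k_active,
                "k_inactive": rec.k_inactive,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["pr", "sd1", "ld", "sd2", "bd"], kind="stable").reset_index(
        drop=True
    )
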