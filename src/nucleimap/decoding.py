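"""Quantitative functional decoding of seed-associated experiments.

Given the subset of database experiments whose foci hit a seed region, each
taxonomy label (behavioural domain or paradigm class) is tested for
enrichment: the count of seed experiments carrying the label against the
label's base rate over the whole database, by an exact binomial test, with
FDR control across the labels of one axis.  Two seeds' profiles are compared
label-by-label with Fisher's exact test on the 2x2 count table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .macm import Experiment
from .volumetry import fdr_adjust

__all__ = ["DecodingProfile", "decode", "contrast_profiles"]


@dataclass
class DecodingProfile:
    """Enrichment of one taxonomy label among seed-associated experiments."""

    label: str
    k: int
    n: int
    k_db: int
    n_db: int
    p_binomial: float
    q_fdr: float
    enriched: bool

    @property
    def base_rate(self) -> float:
        return self.k_db / self.n_db

    @property
    def seed_rate(self) -> float:
        return self.k / self.n if self.n else float("nan")


def _labels_of(e: Experiment, axis: str) -> list[str]:
    if axis == "domains":
        return e.domains
    if axis == "paradigms":
        return e.paradigms
    raise ValueError(f"label axis must be 'domains' or 'paradigms', got {axis!r}")


def decode(
    db: list[Experiment],
    seed_experiments: list[Experiment],
    label_axis: str = "domains",
    alternative: str = "greater",
    q: float = 0.05,
    labels: list[str] | None = None,
) -> list[DecodingProfile]:
    """Per-label exact binomial enrichment of the seed subset.

    For label L with database counts ``k_db / n_db`` (the base rate) and seed
    counts ``k / n``, tests ``Binomial(n, k_db/n_db) >= k`` (one-sided
    enrichment by default, matching the question "more often than by
    chance"); q-values are BH-FDR adjusted across the labels of the axis.
    Labels are not mutually exclusive: an experiment counts once for every
    label it carries.

    Explicitly requested labels absent from the database are skipped with a
    warning rather than given a fabricated p-value.
    """
    if not db:
        raise ValueError("database is empty")
    seed_ids = {e.experiment_id for e in seed_experiments}
    if not seed_ids <= {e.experiment_id for e in db}:
        raise ValueError("seed experiments must be a subset of the database")
    n_db = len(db)
    n = len(seed_experiments)
    db_counts: dict[str, int] = {}
    for e in db:
        for lab in set(_labels_of(e, label_axis)):
            db_counts[lab] = db_counts.get(lab, 0) + 1
    seed_counts: dict[str, int] = {}
    for e in seed_experiments:
        for lab in set(_labels_of(e, label_axis)):
            seed_counts[lab] = seed_counts.get(lab, 0) + 1
    if labels is None:
        labels = sorted(db_counts)
    else:
        missing = [lab for lab in labels if lab not in db_counts]
        for lab in missing:
            warnings.warn(f"label {lab!r} absent from the database; skipped")
        labels = [lab for lab in labels if lab in db_counts]
    pvals = []
    for lab in labels:
        k = seed_counts.get(lab, 0)
        base = db_counts[lab] / n_db
        res = stats.binomtest(k, n, base, alternative=alternative)
        pvals.append(float(res.pvalue))
    adj, rej = fdr_adjust(pvals, q=q)
    profiles = [
        DecodingProfile(
            label=lab,
            k=seed_counts.get(lab, 0),
            n=n,
            k_db=db_counts[lab],
            n_db=n_db,
            p_binomial=p,
            q_fdr=float(a),
            enriched=bool(r),
        )
        for lab, p, a, r in zip(labels, pvals, adj, rej)
    ]
    return sorted(profiles, key=lambda pr: (pr.q_fdr, pr.p_binomial, pr.label))


def contrast_profiles(
    profiles_a: list[DecodingProfile],
    profiles_b: list[DecodingProfile],
    q: float = 0.05,
) -> pd.DataFrame:
    """Differential label table between two decoding profiles.

    Per label, Fisher's exact test on the 2x2 table of seed-subset counts
    ``[[k_a, n_a-k_a], [k_b, n_b-k_b]]``, FDR across labels; the sign column
    says which seed carries the label more often.  Labels with zero counts on
    both sides are skipped.
    """
    a = {p.label: p for p in profiles_a}
    b = {p.label: p for p in profiles_b}
    shared = sorted(set(a) & set(b))
    rows = []
    for lab in shared:
        pa, pb = a[lab], b[lab]
        if pa.k == 0 and pb.k == 0:
            continue
        table = [[pa.k, pa.n - pa.k], [pb.k, pb.n - pb.k]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rate_a = pa.k / pa.n if pa.n else 0.0
        rate_b = pb.k / pb.n if pb.n else 0.0
        rows.append(
            {
                "label": lab,
                "k_a": pa.k,
                "n_a": pa.n,
                "k_b": pb.k,
                "n_b": pb.n,
                "rate_a": rate_a,
                "rate_b": rate_b,
                "direction": "a>b" if rate_a > rate_b else ("b>a" if rate_b > rate_a else "="),
                "p": float(p),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["label", "k_a", "n_a", "k_b", "n_b", "rate_a", "rate_b", "direction", "p"],
    )
    if len(out):
        adj, rej = fdr_adjust(out["p"].to_numpy(), q=q)
        out["q"] = adj
        out["significant"] = rej
    else:
        out["q"] = []
        out["significant"] = []
    return out
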