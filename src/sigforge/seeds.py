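"""Cross-cell-line consistency analysis and seed-gene selection.

A gene induced by hypoxia in *every* cell line is a seed-gene candidate for
in-vivo signature derivation. This module tallies per-gene induction across
lines, applies the seed filters (all lines up, optional protein-coding list,
cohort gene universe), and quantifies how many genes would recur across that
many random gene sets by chance — both by Monte Carlo sampling and by an
exact Poisson-binomial computation that serves as its closed-form oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de_counts import DEResults
from .exceptions import ValidationError


@dataclass
class SeedGeneReport:
    """Per-gene induction tallies across cell lines plus the seed set.

    ``counts`` columns: ``n_lines_up``, ``n_lines_down``; ``induced_in`` maps
    each gene to the cell lines where it was significantly up-regulated.
    """

    counts: pd.DataFrame
    induced_in: dict[str, list[str]]
    n_cell_lines: int
    seed_set: list[str]
    #: genes up in all lines before optional filtering
    all_lines_up: list[str]
    null_summary: dict = field(default_factory=dict)

    def lines_up_at_least(self, m: int) -> pd.Index:
        """Genes up-regulated in at least ``m`` cell lines."""
        return self.counts.index[self.counts["n_lines_up"] >= m]

    def lines_up_exactly(self, m: int) -> pd.Index:
        return self.counts.index[self.counts["n_lines_up"] == m]

    def lines_down_at_least(self, m: int) -> pd.Index:
        return self.counts.index[self.counts["n_lines_down"] >= m]

    def to_json(self, path=None) -> str | None:
        payload = {
            "n_cell_lines": self.n_cell_lines,
            "seed_set": self.seed_set,
            "all_lines_up": self.all_lines_up,
            "n_lines_up": self.counts["n_lines_up"].to_dict(),
            "n_lines_down": self.counts["n_lines_down"].to_dict(),
            "induced_in": self.induced_in,
            "null_summary": self.null_summary,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
            return None
        return text

    def summary(self) -> str:
        k = self.n_cell_lines
        lines = ["Cross-cell-line hypoxia induction consistency"]
        for m in range(k, max(k - 4, 0), -1):
            lines.append(
                f"  up in >= {m} lines: {len(self.lines_up_at_least(m))}"
                f"   down in >= {m} lines: {len(self.lines_down_at_least(m))}"
            )
        lines.append(f"  seed genes (after filters): {len(self.seed_set)}")
        if self.null_summary:
            ns = self.null_summary
            lines.append(
                f"  chance overlap in >= {ns['k_threshold']} sets: "
                f"{ns['mean_overlap']:.2f} +/- {ns['sd_overlap']:.2f} "
                f"({ns['n_reps']} Monte Carlo reps)"
            )
        return "\n".join(lines)


def consistency_counts(de_results: dict[str, DEResults] | list[DEResults],
                       protein_coding: set[str] | None = None,
                       cohort_universe: set[str] | None = None) -> SeedGeneReport:
    """Tally up/down flags per gene across per-line DE results.

    Seed filtering order: genes up in all lines, optionally intersected with
    a protein-coding list, then with the cohort gene universe.
    """
    if isinstance(de_results, list):
        de_results = {f"line{i}": r for i, r in enumerate(de_results)}
    if len(de_results) < 2:
        raise ValidationError("consistency analysis needs >= 2 cell lines")
    names = list(de_results)
    universe = de_results[names[0]].frame.index
    for name in names[1:]:
        if not universe.equals(de_results[name].frame.index):
            raise ValidationError(
                f"gene universe of {name!r} differs from {names[0]!r}"
            )
    up = pd.DataFrame(
        {name: (r.frame["flag"] == "up") for name, r in de_results.items()},
        index=universe,
    )
    down = pd.DataFrame(
        {name: (r.frame["flag"] == "down") for name, r in de_results.items()},
        index=universe,
    )
    counts = pd.DataFrame(
        {"n_lines_up": up.sum(axis=1), "n_lines_down": down.sum(axis=1)},
        index=universe,
    )
    induced_in = {
        g: [name for name in names if up.at[g, name]]
        for g in universe[counts["n_lines_up"] > 0]
    }
    all_up = counts.index[counts["n_lines_up"] == len(names)]
    seed = list(all_up)
    if protein_coding is not None:
        seed = [g for g in seed if g in protein_coding]
    if cohort_universe is not None:
        seed = [g for g in seed if g in cohort_universe]
    return SeedGeneReport(
        counts=counts,
        induced_in=induced_in,
        n_cell_lines=len(names),
        seed_set=seed,
        all_lines_up=list(all_up),
    )


def _check_null_args(universe_size: int, set_sizes, k_threshold: int) -> None:
    if universe_size <= 0:
        raise ValidationError("universe_size must be > 0")
    for sz in set_sizes:
        if sz < 0 or sz > universe_size:
            raise ValidationError(
                f"set size {sz} outside [0, universe_size={universe_size}]"
            )
    if k_threshold > len(set_sizes):
        raise ValidationError("k_threshold exceeds the number of sets")


def mc_overlap_null(universe_size: int, set_sizes: list[int], k_threshold: int,
                    n_reps: int = 1000,
                    seed: int | np.random.Generator | None = None
                    ) -> tuple[float, float]:
    """Monte Carlo null for multi-set gene overlap.

    Each replicate draws one uniform random gene set per observed set size
    (without replacement within a set, independently across sets) and counts
    genes appearing in at least ``k_threshold`` sets. Returns the mean and
    SD of that count over replicates.
    """
    _check_null_args(universe_size, set_sizes, k_threshold)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    overlaps = np.empty(n_reps)
    membership = np.zeros(universe_size, dtype=np.int64)
    for r in range(n_reps):
        membership[:] = 0
        for sz in set_sizes:
            membership[rng.choice(universe_size, size=sz, replace=False)] += 1
        overlaps[r] = int((membership >= k_threshold).sum())
    return float(overlaps.mean()), float(overlaps.std(ddof=1))


def exact_overlap_null(universe_size: int, set_sizes: list[int],
                       k_threshold: int) -> float:
    """Exact expected overlap count under the multi-set null.

    A fixed gene belongs to set ``i`` with probability ``size_i / universe``,
    independently across sets, so its membership count is Poisson-binomial.
    The expectation of the overlap count is ``universe * P(X >= k)``,
    evaluated by exact dynamic-programming convolution.
    """
    _check_null_args(universe_size, set_sizes, k_threshold)
    p = np.asarray(set_sizes, dtype=float) / universe_size
    # DP over P(X = j)
    pmf = np.zeros(len(p) + 1)
    pmf[0] = 1.0
    for pi in p:
        pmf[1:] = pmf[1:] * (1 - pi) + pmf[:-1] * pi
        pmf[0] *= 1 - pi
    tail = float(pmf[k_threshold:].sum())
    return universe_size * tail


def enrichment_fraction(gene_groups: dict[str, set[str]],
                        reference_set: set[str],
                        universe: set[str]) -> dict[str, float | None]:
    """Fraction of each gene tier falling inside a reference gene set.

    Returns per-tier ``|tier & reference| / |tier|`` plus a ``background``
    entry ``|reference| / |universe|``. Empty tiers yield ``None``.
    """
    for name, grp in gene_groups.items():
        if not set(grp) <= universe:
            raise ValidationError(f"tier {name!r} not contained in the universe")
    if not set(reference_set) <= universe:
        raise ValidationError("reference set not contained in the universe")
    out: dict[str, float | None] = {}
    for name, grp in gene_groups.items():
        out[name] = (len(set(grp) & set(reference_set)) / len(grp)) if grp else None
    out["background"] = len(reference_set) / len(universe)
    return out
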