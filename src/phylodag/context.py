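"""5-mer mutability models and the Poisson context branch log-likelihood.

A mutability model assigns each of the 1024 unambiguous nucleotide 5-mers a
normalized targeting rate and a substitution distribution over the three
bases its central base can mutate to.  The Poisson context log-likelihood of
a branch with parent sequence ``l`` and child sequence ``l'`` is

    sum_{j : l_j != l'_j} log(lambda_j)  +  n * log(t_hat)  -  n

where ``lambda_j = gamma_{w(l, j)} * S_{l'_j}^{w(l, j)}``, ``n`` is the
number of differing sites, and the branch length is fixed at its maximum
likelihood estimate ``t_hat = n / sum_j gamma_{w(l, j)}``.  5-mer contexts
are always read from the parent sequence, under the assumption of at most
one mutation per site per branch.  Contexts overlapping the sequence ends
are padded with ``N`` and looked up as the arithmetic mean over all
compatible 5-mers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from typing import Iterable

import numpy as np
import pandas as pd

from ._seq import BASES, IUPAC_TO_BASES
from .sdag import UA, History, HistorySDAG
from .weights import RankingCriterion

N_FIVEMERS = 1024

MODEL_COLUMNS = ["fivemer", "rate", "A", "C", "G", "T"]

_BASE_CODES = str.maketrans({"A": "\x00", "C": "\x01", "G": "\x02", "T": "\x03"})


def all_fivemers() -> list[str]:
    """The 1024 unambiguous nucleotide 5-mers, sorted."""
    return ["".join(p) for p in product(BASES, repeat=5)]


@dataclass
class MutabilityModel:
    """Per-5-mer targeting rates and substitution distributions.

    ``rates[w]`` is the normalized targeting rate of 5-mer ``w``;
    ``substitutions[w][B]`` is the probability that the central base of ``w``
    mutates to ``B`` (zero for ``B`` equal to the central base).
    """

    rates: dict[str, float]
    substitutions: dict[str, dict[str, float]]

    def __post_init__(self):
        expected = set(all_fivemers())
        got = set(self.rates)
        if got != expected or set(self.substitutions) != expected:
            missing = sorted(expected - got)[:3]
            raise ValueError(
                f"model must cover all {N_FIVEMERS} 5-mers exactly once "
                f"(e.g. missing {missing})"
            )
        for w, row in self.substitutions.items():
            if abs(sum(row.values()) - 1.0) > 1e-6:
                raise ValueError(f"substitution row for {w} does not sum to 1")
            if row.get(w[2], 0.0) != 0.0:
                raise ValueError(f"nonzero self-substitution for {w}")

    # -- lookups -----------------------------------------------------------
    def lookup(self, fivemer: str) -> tuple[float, dict[str, float]]:
        """Rate and substitution row, averaging over ambiguity codes.

        A 5-mer containing ambiguity codes (e.g. the ``N`` padding at
        sequence ends) resolves to the arithmetic mean of the values over
        all compatible unambiguous 5-mers.  The central base must be
        unambiguous.
        """
        if len(fivemer) != 5:
            raise ValueError("need a 5-mer")
        if fivemer[2] not in BASES:
            raise ValueError("central base must be unambiguous")
        if all(ch in BASES for ch in fivemer):
            return self.rates[fivemer], self.substitutions[fivemer]
        compatible = [
            "".join(combo)
            for combo in product(*(sorted(IUPAC_TO_BASES[ch]) for ch in fivemer))
        ]
        rate = sum(self.rates[w] for w in compatible) / len(compatible)
        subs = {
            b: sum(self.substitutions[w][b] for w in compatible) / len(compatible)
            for b in BASES
        }
        return rate, subs

    def _rate_array(self) -> np.ndarray:
        # rates indexed by base-4 5-mer code, cached
        arr = getattr(self, "_rate_array_cache", None)
        if arr is None:
            arr = np.empty(N_FIVEMERS)
            for i, w in enumerate(all_fivemers()):
                arr[i] = self.rates[w]
            object.__setattr__(self, "_rate_array_cache", arr)
        return arr

    def rate_profile(self, sequence: str) -> np.ndarray:
        """Targeting rate at every site, with N-padded end contexts."""
        length = len(sequence)
        out = np.empty(length)
        if length >= 5:
            codes = np.frombuffer(
                sequence.translate(_BASE_CODES).encode(), dtype=np.uint8
            ).astype(np.int64)
            window = (
                codes[:-4] * 256
                + codes[1:-3] * 64
                + codes[2:-2] * 16
                + codes[3:-1] * 4
                + codes[4:]
            )
            out[2 : length - 2] = self._rate_array()[window]
        for j in list(range(min(2, length))) + list(range(max(2, length - 2), length)):
            out[j] = self.lookup(context_5mer(sequence, j + 1))[0]
        return out

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            [w, self.rates[w]] + [self.substitutions[w][b] for b in BASES]
            for w in all_fivemers()
        ]
        return pd.DataFrame(rows, columns=MODEL_COLUMNS)

    def to_csv(self, path) -> None:
        # %.17g round-trips IEEE doubles exactly
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MutabilityModel":
        missing = [c for c in MODEL_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"model table missing columns {missing}")
        if frame["fivemer"].duplicated().any():
            dupes = frame.loc[frame["fivemer"].duplicated(), "fivemer"].tolist()[:3]
            raise ValueError(f"duplicate 5-mers in model table (e.g. {dupes})")
        rates = dict(zip(frame["fivemer"], frame["rate"].astype(float)))
        subs = {
            row.fivemer: {b: float(getattr(row, b)) for b in BASES}
            for row in frame.itertuples()
        }
        return cls(rates, subs)

    @classmethod
    def from_csv(cls, path) -> "MutabilityModel":
        return cls.from_frame(
            pd.read_csv(path, dtype={"fivemer": str}, float_precision="round_trip")
        )


def synthetic_model(seed: int) -> MutabilityModel:
    """A seeded random mutability model for tests and simulation.

    Rates are log-normal draws normalized to mean 1; substitution rows are
    Dirichlet(1, 1, 1) over the three non-central bases.
    """
    rng = np.random.default_rng(seed)
    fivemers = all_fivemers()
    raw = rng.lognormal(mean=0.0, sigma=0.8, size=N_FIVEMERS)
    raw /= raw.mean()
    rates = dict(zip(fivemers, raw.tolist()))
    substitutions = {}
    for w in fivemers:
        targets = [b for b in BASES if b != w[2]]
        probs = rng.dirichlet(np.ones(3))
        row = dict.fromkeys(BASES, 0.0)
        row.update(zip(targets, probs.tolist()))
        substitutions[w] = row
    return MutabilityModel(rates, substitutions)


def context_5mer(sequence: str, j: int) -> str:
    """The 5-mer centred at 1-based site ``j``, N-padded at the ends."""
    if not 1 <= j <= len(sequence):
        raise ValueError(f"site {j} out of range for length {len(sequence)}")
    i = j - 1
    window = []
    for k in range(i - 2, i + 3):
        window.append(sequence[k] if 0 <= k < len(sequence) else "N")
    return "".join(window)


def rates_with_ambiguity(model: MutabilityModel, fivemer: str):
    """Mean rate and substitution row over all compatible 5-mers."""
    return model.lookup(fivemer)


def branch_loglik(model: MutabilityModel, parent: str, child: str) -> float:
    """Poisson context log-likelihood of the branch ``parent -> child``.

    Exactly 0 when the sequences are identical.  Returns ``-inf`` when a
    mutated site has zero targeting-substitution rate.
    """
    if len(parent) != len(child):
        raise ValueError("sequence length mismatch")
    diff_sites = [j for j in range(len(parent)) if parent[j] != child[j]]
    n = len(diff_sites)
    if n == 0:
        return 0.0
    total_gamma = 0.0
    log_lambda_sum = 0.0
    for j in range(len(parent)):
        gamma, subs = model.lookup(context_5mer(parent, j + 1))
        total_gamma += gamma
        if parent[j] != child[j]:
            lam = gamma * subs[child[j]]
            if lam <= 0.0:
                return float("-inf")
            log_lambda_sum += math.log(lam)
    t_hat = n / total_gamma
    return log_lambda_sum + n * math.log(t_hat) - n


def context_edge_weight(model: MutabilityModel):
    """Edge function for the DAG engine; UA edges contribute 0."""

    @lru_cache(maxsize=None)
    def pair_loglik(parent_label: str, child_label: str) -> float:
        return branch_loglik(model, parent_label, child_label)

    def edge_fn(parent, child) -> float:
        if parent is UA:
            return 0.0
        return pair_loglik(parent.label, child.label)

    return edge_fn


def context_criterion(model: MutabilityModel) -> RankingCriterion:
    return RankingCriterion(
        edge_fn=context_edge_weight(model),
        direction="max",
        name="context_likelihood",
    )


def history_context_loglik(history: History, model: MutabilityModel) -> float:
    """Sum of branch log-likelihoods over all edges of a history."""
    edge_fn = context_edge_weight(model)
    return history.weight(edge_fn, zero=0.0)
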