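"""Synthetic barcode-community generator with controlled gap structure.

Communities are simulated on a star phylogeny: a uniform-random root gives
rise to one ancestor per species, and each individual is an independently
mutated copy of its species ancestor. Per-branch substitution probabilities
are solved from the requested *pairwise* distances (``target_intra``,
``target_inter``) including a back-mutation/coincidence correction, so the
targets stay honest as expected pairwise p-distances.

Substitutions follow a two-parameter scheme: a hit is a transition with
probability kappa/(kappa+2) and each of the two transversions with
probability 1/(kappa+2).

``overlap_mode`` plants one haplotype of the first species verbatim into
the second species, forcing a heterospecific zero-distance pair — the
regime in which distance thresholds cannot cleanly separate species.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import DomainError
from .seq_model import LabeledAlignment

BASES = "ACGT"
# transition partner of each base (A<->G, C<->T)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

MAX_P = 0.75


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a simulated community."""

    n_species: int
    per_species_n: tuple[int, ...]
    seq_length: int = 600
    target_intra: float = 0.01
    target_inter: float = 0.15
    kappa: float = 2.0
    overlap_mode: bool = False
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "per_species_n", tuple(self.per_species_n))
        if self.n_species < 1 or len(self.per_species_n) != self.n_species:
            raise DomainError(
                f"per_species_n must list {self.n_species} counts, "
                f"got {len(self.per_species_n)}"
            )
        if any(k < 1 for k in self.per_species_n):
            raise DomainError("per-species counts must be >= 1")
        if self.seq_length < 1:
            raise DomainError("seq_length must be >= 1")
        if self.kappa <= 0:
            raise DomainError(f"kappa must be > 0, got {self.kappa}")
        if not self.overlap_mode:
            if not (0.0 <= self.target_intra < self.target_inter <= MAX_P):
                raise DomainError(
                    "need 0 <= target_intra < target_inter <= "
                    f"{MAX_P} (got {self.target_intra}, {self.target_inter})"
                )
        else:
            if not (0.0 <= self.target_intra <= MAX_P and 0.0 <= self.target_inter <= MAX_P):
                raise DomainError("targets must lie in [0, 0.75]")
        if self.overlap_mode and (self.n_species < 2 or min(self.per_species_n[:2]) < 1):
            raise DomainError("overlap_mode needs at least 2 species")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation run."""

    spec: CommunitySpec
    seed: int
    root: str
    ancestors: dict[str, str]
    branch_p_intra: float
    branch_p_inter: float
    mutation_counts: dict[str, int] = field(default_factory=dict)
    overlap_pair: tuple[str, str] | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spec": asdict(self.spec),
            "seed": self.seed,
            "root": self.root,
            "ancestors": self.ancestors,
            "branch_p_intra": self.branch_p_intra,
            "branch_p_inter": self.branch_p_inter,
            "mutation_counts": self.mutation_counts,
            "overlap_pair": list(self.overlap_pair) if self.overlap_pair else None,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def mutate_sequence(
    seq: str, expected_p: float, kappa: float, rng: np.random.Generator
) -> str:
    """Substitute each site independently with probability ``expected_p``.

    A substituted site becomes the transition partner with probability
    kappa/(kappa+2) and each transversion partner with probability
    1/(kappa+2).
    """
    if not 0.0 <= expected_p < MAX_P:
        raise DomainError(
            f"expected_p must be in [0, {MAX_P}), got {expected_p}"
        )
    if kappa <= 0:
        raise DomainError(f"kappa must be > 0, got {kappa}")
    if expected_p == 0.0:
        return seq
    hits = rng.random(len(seq)) < expected_p
    p_ts = kappa / (kappa + 2.0)
    out = list(seq)
    for i in np.flatnonzero(hits):
        base = out[i]
        if base not in _TRANSITION:  # leave N/- untouched
            continue
        u = rng.random()
        if u < p_ts:
            out[i] = _TRANSITION[base]
        elif u < p_ts + (1.0 - p_ts) / 2.0:
            out[i] = _TRANSVERSIONS[base][0]
        else:
            out[i] = _TRANSVERSIONS[base][1]
    return "".join(out)


def branch_p_for_pairwise(target_d: float, kappa: float) -> float:
    """Per-branch substitution probability giving expected tip-to-tip p-distance.

    Two branches of per-site probability p hang off a shared ancestor. A
    site differs between the tips iff exactly one branch hit it, or both
    hit it and the substitutions landed on different bases:

        D(p) = 2 p (1-p) + p^2 (1 - s),   s = (kappa^2 + 2) / (kappa + 2)^2

    where s is the probability two independent substitutions of the same
    base coincide. Solving the quadratic for p in [0, 1).
    """
    if not 0.0 <= target_d <= MAX_P:
        raise DomainError(f"target distance must be in [0, {MAX_P}]")
    if target_d == 0.0:
        return 0.0
    s = (kappa**2 + 2.0) / (kappa + 2.0) ** 2
    a = 1.0 + s  # coefficient of p^2 in D(p) = 2p - (1+s) p^2
    disc = 1.0 - a * target_d
    if disc <= 0:
        raise DomainError(
            f"target distance {target_d} unattainable for kappa={kappa}"
        )
    return (1.0 - math.sqrt(disc)) / a


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def simulate_community(
    spec: CommunitySpec,
) -> tuple[LabeledAlignment, SyntheticTruth]:
    """Simulate a labeled community; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    root = _random_sequence(spec.seq_length, rng)
    # inter target covers ancestor-to-ancestor divergence; individuals add
    # their own intra-level noise on top, widening realized inter slightly
    p_inter = branch_p_for_pairwise(spec.target_inter, spec.kappa)
    p_intra = branch_p_for_pairwise(spec.target_intra, spec.kappa)
    species_names = [f"species_{k + 1:02d}" for k in range(spec.n_species)]
    ancestors = {
        name: mutate_sequence(root, p_inter, spec.kappa, rng)
        for name in species_names
    }
    ids, seqs, labels = [], [], []
    for name, count in zip(species_names, spec.per_species_n):
        for j in range(count):
            ids.append(f"{name}_{j + 1:03d}")
            seqs.append(mutate_sequence(ancestors[name], p_intra, spec.kappa, rng))
            labels.append(name)
    truth = SyntheticTruth(
        spec=spec,
        seed=spec.seed,
        root=root,
        ancestors=ancestors,
        branch_p_intra=p_intra,
        branch_p_inter=p_inter,
    )
    if spec.overlap_mode:
        donor_idx = 0  # first member of species 1
        recipient_idx = spec.per_species_n[0]  # first member of species 2
        seqs[recipient_idx] = seqs[donor_idx]
        truth.overlap_pair = (ids[donor_idx], ids[recipient_idx])
    for seq_id, s, label in zip(ids, seqs, labels):
        truth.mutation_counts[seq_id] = sum(
            1 for x, y in zip(s, ancestors[label]) if x != y
        )
    aln = LabeledAlignment(ids=ids, seqs=seqs, labels=labels, locus="synthetic")
    return aln, truth
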