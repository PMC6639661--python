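"""Ground-truth synthetic OTU communities for end-to-end verification.

The generator realizes the idealized assembly regimes the distance analysis is
meant to detect, in a community of N OTUs over an alignment of length L with M
conserved columns:

* neutral rare OTUs scatter at random in sequence space — free columns i.i.d.
  uniform over the four bases, so nearest-modal distances concentrate in a
  bell just below 3(L-M)/(4L);
* niche rare OTUs are few-mutation satellites of modal OTUs — each copies a
  randomly chosen modal sequence and applies u ~ Uniform{1..r} point mutations
  at distinct free positions, so its nearest-modal distance is at most r/L;
* a hybrid community mixes the two: a fraction ``alpha`` of the rare OTUs is
  niche-derived, the rest neutral.

Abundances are drawn from a skewed (lognormal-weight) model and adjusted so
that the designated modal OTUs sit above the threshold k and every rare OTU
below it; the modal/rare partition at k recovers the design exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

from .distance import partition_modal_rare
from .errors import GenerationError
from .io import AlignedOtuTable

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Labels attached to each generated OTU.
MODAL, NICHE_DERIVED, NEUTRAL_DERIVED = "modal", "niche", "neutral"


@dataclass(frozen=True)
class SyntheticCommunitySpec:
    """Generative parameters of a synthetic community.

    ``alpha`` is the niche fraction: the share of rare OTUs that are
    few-mutation satellites of modal OTUs (0 = purely neutral, 1 = purely
    niche). Defaults describe a gut-like sample: 600 OTUs of aligned length
    400 with 100 conserved columns, 8 modal OTUs, niche radius 3 mutations,
    modal threshold 5%.
    """

    alpha: float
    n_otus: int = 600
    length: int = 400
    n_conserved: int = 100
    n_modal: int = 8
    niche_radius: int = 3
    k: float = 0.05
    abundance_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not 0 <= self.n_conserved <= self.length:
            raise ValueError("n_conserved must lie in [0, length]")
        if self.n_modal < 1 or self.n_modal >= self.n_otus:
            raise ValueError("need 1 <= n_modal < n_otus")
        if self.niche_radius < 1:
            raise ValueError("niche_radius must be >= 1")
        if self.alpha > 0 and self.niche_radius > self.length - self.n_conserved:
            raise ValueError("niche_radius exceeds the number of free columns")
        if not 0.0 < self.k < 1.0:
            raise ValueError(f"k must lie in (0, 1), got {self.k}")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_otus": self.n_otus,
            "length": self.length,
            "n_conserved": self.n_conserved,
            "n_modal": self.n_modal,
            "niche_radius": self.niche_radius,
            "k": self.k,
            "abundance_sigma": self.abundance_sigma,
            "seed": self.seed,
        }


def generate_template(
    length: int, n_conserved: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Community template: fixed bases at conserved positions, free elsewhere.

    Returns the template as base codes 0..3 and a boolean conserved mask;
    ``n_conserved`` positions are chosen uniformly without replacement and
    their bases are shared by every community member.
    """
    if not 0 <= n_conserved <= length:
        raise ValueError(f"n_conserved={n_conserved} outside [0, {length}]")
    template = rng.integers(0, 4, length, dtype=np.uint8)
    mask = np.zeros(length, dtype=bool)
    if n_conserved:
        mask[rng.choice(length, n_conserved, replace=False)] = True
    return template, mask


def _decode(codes: np.ndarray) -> str:
    return bytes(_BASES[codes]).decode("ascii")


def generate_community(
    spec: SyntheticCommunitySpec, rng: np.random.Generator | None = None
) -> Tuple[AlignedOtuTable, dict]:
    """Generate sequences and ground-truth labels (abundances left unset).

    Modal OTUs come first in the table, then niche-derived rares, then
    neutral rares. All sequences are distinct (collisions are regenerated, up
    to a retry cap). Returns the table and a dict otu_id -> label in
    {"modal", "niche", "neutral"}.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    template, mask = generate_template(spec.length, spec.n_conserved, rng)
    free = np.flatnonzero(~mask)
    n_rare = spec.n_otus - spec.n_modal
    n_niche = int(round(spec.alpha * n_rare))

    seen: set = set()
    retry_cap = 100

    def admit(draw):
        for _ in range(retry_cap):
            seq = draw()
            key = seq.tobytes()
            if key not in seen:
                seen.add(key)
                return seq
        raise GenerationError(
            "could not generate a distinct sequence within the retry cap; "
            "the free-column alphabet is likely exhausted"
        )

    def draw_random():
        seq = template.copy()
        seq[free] = rng.integers(0, 4, free.size, dtype=np.uint8)
        return seq

    modal_seqs = [admit(draw_random) for _ in range(spec.n_modal)]

    def draw_satellite():
        parent = modal_seqs[int(rng.integers(0, spec.n_modal))]
        seq = parent.copy()
        u = int(rng.integers(1, spec.niche_radius + 1))
        pos = rng.choice(free, u, replace=False)
        # substitute with a different base so exactly u columns mismatch
        seq[pos] = (seq[pos] + rng.integers(1, 4, u, dtype=np.uint8)) % 4
        return seq

    niche_seqs = [admit(draw_satellite) for _ in range(n_niche)]
    neutral_seqs = [admit(draw_random) for _ in range(n_rare - n_niche)]

    width = len(str(spec.n_otus))
    otu_ids, sequences, labels = [], [], {}
    for group, label, prefix in (
        (modal_seqs, MODAL, "modal"),
        (niche_seqs, NICHE_DERIVED, "rare"),
        (neutral_seqs, NEUTRAL_DERIVED, "rare"),
    ):
        for seq in group:
            otu_id = f"{prefix}_{len(otu_ids) + 1:0{width}d}"
            otu_ids.append(otu_id)
            sequences.append(_decode(seq))
            labels[otu_id] = label

    table = AlignedOtuTable(
        sample_id=f"sim-a{spec.alpha:g}-s{spec.seed}",
        otu_ids=otu_ids,
        sequences=sequences,
        abundances=None,
    )
    return table, labels


def assign_abundances(
    table: AlignedOtuTable,
    spec: SyntheticCommunitySpec,
    rng: np.random.Generator | None = None,
) -> AlignedOtuTable:
    """Skewed read counts that realize the designed modal/rare split exactly.

    The first ``spec.n_modal`` rows of the table are the designated modal
    OTUs (the order produced by :func:`generate_community`). Rare counts are
    small positive integers with lognormal weights; modal counts come from
    lognormal-weighted target shares above k and are bumped until
    ``partition_modal_rare`` at ``spec.k`` recovers the design exactly.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n_modal, k = spec.n_modal, spec.k
    if n_modal * k >= 1.0:
        raise ValueError(
            f"infeasible threshold: {n_modal} modal OTUs at k={k} would need "
            f"total relative abundance {n_modal * k:.2f} >= 1"
        )
    n_rare = table.n_otus - n_modal
    if n_rare < 1:
        raise ValueError("table has no rare OTUs")

    rare = np.maximum(
        1, np.rint(rng.lognormal(0.0, spec.abundance_sigma, n_rare))
    ).astype(np.int64)
    total_rare = int(rare.sum())

    # modal target shares: each at least margin*k, skewed lognormal extras
    margin = min(1.1, (1.0 + n_modal * k) / (2.0 * n_modal * k))
    base = margin * k
    bulk = min(0.95, max(0.6, 2.2 * n_modal * k))
    if bulk <= n_modal * base:
        bulk = (n_modal * base + 1.0) / 2.0
    weights = rng.lognormal(0.0, spec.abundance_sigma, n_modal)
    shares = base + (weights / weights.sum()) * (bulk - n_modal * base)
    scale = total_rare / (1.0 - bulk)
    modal = np.ceil(shares * scale).astype(np.int64)

    for _ in range(500):
        total = total_rare + int(modal.sum())
        floor_k = int(np.floor(k * total))
        changed = False
        low = modal < floor_k + 1  # strictly above k, safe under float compare
        if low.any():
            modal[low] = floor_k + 1
            changed = True
        if int(rare.max()) > floor_k - 1:
            modal = np.ceil(modal * 1.3).astype(np.int64)
            changed = True
        if not changed:
            break
    else:
        raise GenerationError("abundance assignment did not converge")

    abundances = [int(c) for c in modal] + [int(c) for c in rare]
    result = replace(table, abundances=abundances)

    part = partition_modal_rare(result, k=k, mode="fraction_of_total")
    designed = set(table.otu_ids[:n_modal])
    if part.modal_ids != designed:
        raise GenerationError(
            "abundance assignment failed to realize the designed partition"
        )
    return result


def simulate_community(
    spec: SyntheticCommunitySpec,
) -> Tuple[AlignedOtuTable, dict]:
    """Full community: sequences, ground-truth labels and abundances."""
    rng = np.random.default_rng(spec.seed)
    table, labels = generate_community(spec, rng)
    table = assign_abundances(table, spec, rng)
    return table, labels
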