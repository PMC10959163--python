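"""Synthetic association/similarity data with planted block structure.

The generator emulates the shape of curated miRNA-disease inputs: two
symmetric similarity matrices in [0, 1] with unit diagonal, and a sparse
binary association matrix whose links correlate with planted blocks.  Each
miRNA and each disease is assigned one of ``n_blocks`` latent blocks;
matching-block pairs associate with probability ``p_in`` and mismatched pairs
with ``p_out``.  Similarity between two entities is a noisy indicator of
shared block membership, so the similarity features genuinely carry the
signal that determines the associations — the recovery task a predictor must
solve.

A configurable fraction of entities is held out as "new" (their associations
withheld from training) and a fraction of old-entity associations is held out
as novel links, mirroring the four association-novelty test regimes
(Tp/Td/Tm/Tn).  A fraction of off-diagonal similarity entries is zero-masked
to exercise the GIP fallback branch of similarity integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .similarity import AssociationMatrix, InputError, SimilarityMatrix

__all__ = ["SyntheticSpec", "SyntheticData", "generate"]


@dataclass
class SyntheticSpec:
    """Parameters of the planted-block generator.

    Defaults define the standard recoverability fixture: 200 miRNAs x 150
    diseases in 5 blocks, a 15x association-rate contrast between matched and
    mismatched blocks, strong but noisy block signal in the similarities, and
    15% of each entity type held out as new.
    """

    n_mirna: int = 200
    n_disease: int = 150
    n_blocks: int = 5
    p_in: float = 0.3
    p_out: float = 0.02
    similarity_signal: float = 0.8
    noise_sd: float = 0.05
    base_similarity: float = 0.1
    zero_mask_fraction: float = 0.2
    new_fraction_mirna: float = 0.15
    new_fraction_disease: float = 0.15
    holdout_fraction_old: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_mirna < 2 or self.n_disease < 2:
            raise InputError("need at least 2 miRNAs and 2 diseases")
        if self.n_blocks < 1 or self.n_blocks > min(self.n_mirna, self.n_disease):
            raise InputError("n_blocks must be in [1, min(n_mirna, n_disease)]")
        for name in ("p_in", "p_out", "similarity_signal", "base_similarity",
                     "zero_mask_fraction", "holdout_fraction_old"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name}={v} outside [0, 1]")
        if self.p_in < self.p_out:
            raise InputError("p_in must be >= p_out")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be nonnegative")
        for name in ("new_fraction_mirna", "new_fraction_disease"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise InputError(f"{name}={v} outside [0, 1)")


@dataclass
class SyntheticData:
    """Output bundle of :func:`generate`."""

    assoc: AssociationMatrix
    mirna_sim: SimilarityMatrix
    disease_sim: SimilarityMatrix
    mirna_blocks: np.ndarray
    disease_blocks: np.ndarray
    old_mirnas: list[str]
    new_mirnas: list[str]
    old_diseases: list[str]
    new_diseases: list[str]
    old_pairs: list[tuple[str, str]] = field(default_factory=list)
    new_pairs: list[tuple[str, str]] = field(default_factory=list)


def _block_similarity(
    blocks: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> np.ndarray:
    same = (blocks[:, None] == blocks[None, :]).astype(float)
    base = spec.similarity_signal * same + (1.0 - spec.similarity_signal) * spec.base_similarity
    noise = rng.normal(0.0, spec.noise_sd, size=base.shape) if spec.noise_sd > 0 else 0.0
    s = np.clip(base + noise, 0.0, 1.0)
    s = (s + s.T) / 2.0
    if spec.zero_mask_fraction > 0:
        n = len(blocks)
        iu, ju = np.triu_indices(n, k=1)
        n_mask = int(round(spec.zero_mask_fraction * len(iu)))
        pick = rng.choice(len(iu), size=n_mask, replace=False)
        s[iu[pick], ju[pick]] = 0.0
        s[ju[pick], iu[pick]] = 0.0
    np.fill_diagonal(s, 1.0)
    return s


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Draw one synthetic dataset; deterministic given ``spec.seed``.

    Returns the full association matrix together with the old/new entity
    registries and the training (``old_pairs``) vs held-out (``new_pairs``)
    positive associations.  Held-out positives are: every positive touching a
    new entity, plus ``holdout_fraction_old`` of the old-old positives.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    mirnas = [f"mirna-{i:03d}" for i in range(spec.n_mirna)]
    diseases = [f"disease-{j:03d}" for j in range(spec.n_disease)]
    mb = rng.integers(0, spec.n_blocks, size=spec.n_mirna)
    db = rng.integers(0, spec.n_blocks, size=spec.n_disease)

    match = mb[:, None] == db[None, :]
    prob = np.where(match, spec.p_in, spec.p_out)
    a = (rng.random(prob.shape) < prob).astype(np.int8)
    assoc = AssociationMatrix(mirnas=mirnas, diseases=diseases, values=a)

    msim = SimilarityMatrix(mirnas, _block_similarity(mb, spec, rng))
    dsim = SimilarityMatrix(diseases, _block_similarity(db, spec, rng))

    n_new_m = int(round(spec.new_fraction_mirna * spec.n_mirna))
    n_new_d = int(round(spec.new_fraction_disease * spec.n_disease))
    new_m_idx = set(rng.choice(spec.n_mirna, size=n_new_m, replace=False).tolist())
    new_d_idx = set(rng.choice(spec.n_disease, size=n_new_d, replace=False).tolist())
    old_mirnas = [m for i, m in enumerate(mirnas) if i not in new_m_idx]
    new_mirnas = [m for i, m in enumerate(mirnas) if i in new_m_idx]
    old_diseases = [d for j, d in enumerate(diseases) if j not in new_d_idx]
    new_diseases = [d for j, d in enumerate(diseases) if j in new_d_idx]

    ii, jj = np.nonzero(a)
    old_old = [
        k for k in range(len(ii))
        if ii[k] not in new_m_idx and jj[k] not in new_d_idx
    ]
    n_hold = int(round(spec.holdout_fraction_old * len(old_old)))
    held = set(
        rng.choice(old_old, size=n_hold, replace=False).tolist()
    ) if n_hold else set()

    old_pairs, new_pairs = [], []
    for k in range(len(ii)):
        pair = (mirnas[ii[k]], diseases[jj[k]])
        if ii[k] in new_m_idx or jj[k] in new_d_idx or k in held:
            new_pairs.append(pair)
        else:
            old_pairs.append(pair)

    return SyntheticData(
        assoc=assoc,
        mirna_sim=msim,
        disease_sim=dsim,
        mirna_blocks=mb,
        disease_blocks=db,
        old_mirnas=old_mirnas,
        new_mirnas=new_mirnas,
        old_diseases=old_diseases,
        new_diseases=new_diseases,
        old_pairs=old_pairs,
        new_pairs=new_pairs,
    )
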