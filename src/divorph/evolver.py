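"""Protein divergence simulator: LG substitutions + gamma rates + indels.

Sequences evolve along a rooted tree with branch lengths in expected
substitutions per site. Per-site relative rates are drawn once at the
root (invariant with probability ``p_inv``, otherwise Gamma with mean 1)
and inherited down the tree; inserted sites draw fresh rates. Substitution
is sampled exactly from the matrix exponential of the normalized LG
generator, so branch lengths keep their usual interpretation.

With ``ins_rate = del_rate = 0`` the simulation is substitution-only and
descendant length equals root length exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .io_formats import PhyloTree, ProteinRecord, Provenance
from .lg_data import AA_ORDER, LG_FREQS, lg_generator

__all__ = [
    "EvolutionParams",
    "SimulatedFamily",
    "lg_transition_matrix",
    "draw_site_rates",
    "evolve_branch",
    "evolve_tree",
]

_AA_IDX = {a: i for i, a in enumerate(AA_ORDER)}


@dataclass(frozen=True)
class EvolutionParams:
    """Knobs of the divergence simulation.

    ``alpha`` is the gamma shape of among-site rate variation (mean fixed
    at 1); the replication sweep uses {0.1, 0.3, 0.5, 1} but any positive
    value is accepted. ``ins_rate``/``del_rate`` are events per site per
    unit branch length; a single published "indel rate" value maps to both
    processes having that rate. Indel lengths are geometric with mean
    ``indel_len_mean`` (the source analyses leave the length law
    unspecified; this is a documented knob).
    """

    alpha: float
    p_inv: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    indel_len_mean: float = 3.0
    substitution_model: str = "LG"
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError("alpha must be positive and finite")
        if not 0.0 <= self.p_inv <= 1.0:
            raise ValueError("p_inv must be in [0, 1]")
        if self.ins_rate < 0 or self.del_rate < 0:
            raise ValueError("indel rates must be >= 0")
        if self.indel_len_mean < 1:
            raise ValueError("indel_len_mean must be >= 1")
        if self.substitution_model != "LG":
            raise ValueError("only the LG substitution model is supported")


@dataclass
class SimulatedFamily:
    """Root plus its simulated descendants, one per terminal branch."""

    root: ProteinRecord
    descendants: dict[str, ProteinRecord]
    params: EvolutionParams
    #: per-taxon realized event diagnostics:
    #: {taxon: {"substitution_events", "insertions", "deletions"}}
    events: dict[str, dict[str, int]] = field(default_factory=dict)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.descendants.values())


# --- LG spectral machinery (computed once) ---------------------------------

_SPECTRAL: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None


def _spectral() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecomposition of the normalized LG generator.

    Q is reversible, so D^{1/2} Q D^{-1/2} is symmetric and we can use a
    stable symmetric eigensolver. Returns (eigenvalues, V, V^{-1}) with
    Q = V diag(lam) V^{-1}.
    """
    global _SPECTRAL
    if _SPECTRAL is None:
        q = lg_generator()
        d = np.sqrt(LG_FREQS)
        sym = (q * d[:, None]) / d[None, :]
        lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
        v = u / d[:, None]
        vinv = u.T * d[None, :]
        _SPECTRAL = (lam, v, vinv)
    return _SPECTRAL


def lg_transition_matrix(t: float) -> np.ndarray:
    """Transition matrix expm(Q t) for the normalized LG generator.

    ``t`` is branch length times relative site rate; rows sum to 1.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    lam, v, vinv = _spectral()
    p = (v * np.exp(lam * t)[None, :]) @ vinv
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


def draw_site_rates(
    n_sites: int,
    alpha: float,
    p_inv: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-site relative rates: 0 with probability ``p_inv``, else
    continuous Gamma(shape=alpha, mean=1)."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    rates = rng.gamma(shape=alpha, scale=1.0 / alpha, size=n_sites)
    if p_inv > 0:
        rates[rng.random(n_sites) < p_inv] = 0.0
    return rates


def _encode(seq: str) -> np.ndarray:
    # X (unknown) sites are carried as index 0 stand-ins would bias
    # composition; instead replace X by a draw from equilibrium upfront.
    return np.array([_AA_IDX.get(c, -1) for c in seq], dtype=np.int64)


def _decode(idx: np.ndarray) -> str:
    return "".join(AA_ORDER[i] for i in idx)


def _substitute(
    idx: np.ndarray,
    rates: np.ndarray,
    t: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exact per-site substitution draw from expm(Q * rate_i * t)."""
    lam, v, vinv = _spectral()
    variable = rates > 0
    if t == 0 or not variable.any():
        return idx.copy()
    out = idx.copy()
    sub_idx = idx[variable]
    sub_rates = rates[variable]
    # per-site transition row: row_i = V[seq_i, :] * exp(lam * r_i * t) @ Vinv
    expfac = np.exp(np.outer(sub_rates * t, lam))        # (L, 20)
    rows = np.einsum("sk,sk,kj->sj", v[sub_idx, :], expfac, vinv)
    np.clip(rows, 0.0, None, out=rows)
    rows /= rows.sum(axis=1, keepdims=True)
    cum = np.cumsum(rows, axis=1)
    u = rng.random(len(sub_idx))
    draws = (cum < u[:, None]).sum(axis=1)
    np.clip(draws, 0, 19, out=draws)
    out[variable] = draws
    return out


def _draw_indel_length(rng: np.random.Generator, mean: float) -> int:
    if mean <= 1.0:
        return 1
    return int(rng.geometric(1.0 / mean))


def evolve_branch(
    seq: str,
    rates: np.ndarray,
    t: float,
    params: EvolutionParams,
    rng: np.random.Generator,
) -> tuple[str, np.ndarray, dict[str, int]]:
    """Evolve a sequence along one branch of length ``t``.

    Substitutions are applied site-wise from the exact transition matrix;
    indel event counts are Poisson in (rate x starting length x t), applied
    in random order at uniform positions with geometric lengths. Inserted
    residues come from LG equilibrium and get fresh site rates. The
    sequence never shrinks below length 1.

    Returns the new sequence, its aligned rate vector, and realized event
    counts (substitution_events is a model-consistent Poisson draw used
    for diagnostics, independent of the sampled residues).
    """
    if not seq:
        raise ValueError("cannot evolve an empty sequence")
    if len(seq) != len(rates):
        raise ValueError("rates must align with sequence")
    if t < 0:
        raise ValueError("branch length must be >= 0")

    idx = _encode(seq)
    unknown = idx < 0
    if unknown.any():
        idx[unknown] = rng.choice(20, size=int(unknown.sum()), p=LG_FREQS)

    idx = _substitute(idx, rates, t, rng)
    rates = rates.copy()

    n_events = int(rng.poisson(rates.sum() * t))
    n_ins = int(rng.poisson(params.ins_rate * len(seq) * t))
    n_del = int(rng.poisson(params.del_rate * len(seq) * t))

    ops = ["I"] * n_ins + ["D"] * n_del
    rng.shuffle(ops)
    realized_ins = realized_del = 0
    for op in ops:
        length = _draw_indel_length(rng, params.indel_len_mean)
        if op == "I":
            pos = int(rng.integers(0, len(idx) + 1))
            residues = rng.choice(20, size=length, p=LG_FREQS)
            new_rates = draw_site_rates(length, params.alpha, params.p_inv, rng)
            idx = np.concatenate([idx[:pos], residues, idx[pos:]])
            rates = np.concatenate([rates[:pos], new_rates, rates[pos:]])
            realized_ins += 1
        else:
            if len(idx) <= 1:
                continue  # never shrink below one residue
            pos = int(rng.integers(0, len(idx)))
            length = min(length, len(idx) - pos, len(idx) - 1)
            if length < 1:
                continue
            idx = np.concatenate([idx[:pos], idx[pos + length:]])
            rates = np.concatenate([rates[:pos], rates[pos + length:]])
            realized_del += 1

    events = {
        "substitution_events": n_events,
        "insertions": realized_ins,
        "deletions": realized_del,
    }
    return _decode(idx), rates, events


def evolve_tree(
    root: ProteinRecord,
    tree: PhyloTree,
    params: EvolutionParams,
    rng: np.random.Generator | None = None,
) -> SimulatedFamily:
    """Simulate one family: pre-order traversal applying
    :func:`evolve_branch` along every edge.

    Site rates and sequence state are inherited at internal nodes.
    Descendants carry ``provenance=simulated`` and ids
    ``{root.id}|{taxon_label}``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rates0 = draw_site_rates(len(root.sequence), params.alpha, params.p_inv, rng)

    descendants: dict[str, ProteinRecord] = {}
    all_events: dict[str, dict[str, int]] = {}

    def recurse(node, seq: str, rates: np.ndarray,
                acc: dict[str, int]) -> None:
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            new_seq, new_rates, ev = evolve_branch(seq, rates, t, params, rng)
            new_acc = {k: acc[k] + ev[k] for k in acc}
            if child.is_leaf():
                label = child.taxon.label
                descendants[label] = ProteinRecord(
                    id=f"{root.id}|{label}",
                    sequence=new_seq,
                    provenance=Provenance.SIMULATED,
                    taxon_label=label,
                )
                all_events[label] = new_acc
            else:
                recurse(child, new_seq, new_rates, new_acc)

    zero = {"substitution_events": 0, "insertions": 0, "deletions": 0}
    recurse(tree.dendropy_tree.seed_node, root.sequence, rates0, dict(zero))
    return SimulatedFamily(root=root, descendants=descendants,
                           params=params, events=all_events)
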