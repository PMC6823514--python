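"""Neutral sequence evolution along a tree under HKY or GTR.

Branch lengths are expected substitutions per site; the rate matrix is scaled
so one unit of branch length produces one expected substitution per site.
Sites evolve independently (no rate heterogeneity, no indels).  Transition
matrices come from an eigendecomposition of the pi-symmetrized generator,
which is always real-diagonalizable for a reversible model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trees import SpeciesTree, SUBS, UnitError

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """ACGT string -> uint8 array (255 for anything else)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lookup[arr].tobytes().decode("ascii")


@dataclass
class SubstitutionModel:
    """Reversible nucleotide model (HKY or GTR) scaled to rate 1."""

    model_id: str
    exchangeabilities: np.ndarray  # 6-vector: AC, AG, AT, CG, CT, GT
    frequencies: np.ndarray        # pi_A, pi_C, pi_G, pi_T
    _eig: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("base frequencies must sum to 1")
        if np.any(self.frequencies < 0) or (self.frequencies > 0).sum() < 2:
            raise ValueError("need non-negative frequencies with >= 2 states")
        if np.any(self.exchangeabilities < 0):
            raise ValueError("exchangeabilities must be non-negative")

    @classmethod
    def hky(cls, kappa: float = 2.0, frequencies=(0.25, 0.25, 0.25, 0.25)):
        """HKY85: transitions (A<->G, C<->T) weighted by kappa."""
        ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        return cls("HKY", ex, np.asarray(frequencies, dtype=float))

    @classmethod
    def gtr(cls, exchangeabilities, frequencies):
        return cls("GTR", np.asarray(exchangeabilities, dtype=float),
                   np.asarray(frequencies, dtype=float))

    @classmethod
    def jc69(cls):
        return cls.hky(kappa=1.0)

    def rate_matrix(self) -> np.ndarray:
        """Generator Q with rows summing to 0 and mean rate 1."""
        pi = self.frequencies
        s, pairs = self.exchangeabilities, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        Q = np.zeros((4, 4))
        for rate, (i, j) in zip(s, pairs):
            Q[i, j] = rate * pi[j]
            Q[j, i] = rate * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -(pi * np.diag(Q)).sum()
        return Q / mean_rate

    def _eigendecomposition(self):
        # zero-frequency states are outside the support: they are never
        # visited, so the decomposition is done on the support submatrix
        if self._eig is None:
            support = np.nonzero(self.frequencies > 0)[0]
            pi = self.frequencies[support]
            Q = self.rate_matrix()[np.ix_(support, support)]
            sqrt_pi = np.sqrt(pi)
            S = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]  # symmetric
            w, V = np.linalg.eigh((S + S.T) / 2.0)
            left = V.T * sqrt_pi[None, :]
            right = V / sqrt_pi[:, None]
            self._eig = (support, w, right, left)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows sum to 1 (identity rows off the support)."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        support, w, right, left = self._eigendecomposition()
        Ps = (right * np.exp(w * t)[None, :]) @ left
        Ps = np.clip(Ps, 0.0, None)
        Ps /= Ps.sum(axis=1, keepdims=True)
        P = np.eye(4)
        P[np.ix_(support, support)] = Ps
        if support.size < 4:
            for s in np.setdiff1d(np.arange(4), support):
                P[s, s] = 1.0
        return P


@dataclass
class SimulatedAlignment:
    """Leaf sequences from one replicate of one scenario."""

    sequences: dict          # leaf label -> ACGT string
    length: int
    replicate_id: int = 0
    seed: int | None = None
    scenario_id: str = ""

    def encoded(self) -> dict:
        return {k: encode(v) for k, v in self.sequences.items()}

    def to_fasta(self) -> str:
        return "".join(f">{k}\n{v}\n" for k, v in sorted(self.sequences.items()))


def simulate_root_sequence(length: int, frequencies=(0.25, 0.25, 0.25, 0.25),
                           rng: np.random.Generator | int | None = None) -> np.ndarray:
    """I.i.d. root states drawn from the base-frequency vector."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(rng)
    freqs = np.asarray(frequencies, dtype=float)
    return rng.choice(4, size=length, p=freqs / freqs.sum()).astype(np.uint8)


def _evolve_along_branch(parent_states: np.ndarray, P: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    child = np.empty_like(parent_states)
    for s in range(4):
        idx = np.nonzero(parent_states == s)[0]
        if idx.size:
            child[idx] = rng.choice(4, size=idx.size, p=P[s]).astype(np.uint8)
    return child


def evolve(tree: SpeciesTree, model: SubstitutionModel, root_sequence,
           rng: np.random.Generator | int | None = None,
           replicate_id: int = 0, scenario_id: str = "") -> SimulatedAlignment:
    """Evolve a root sequence down a substitutions-unit tree.

    ``root_sequence`` may be an ACGT string or a uint8 state array.
    """
    if tree.unit != SUBS:
        raise UnitError("evolve needs branch lengths in substitutions/site")
    rng = np.random.default_rng(rng)
    states = encode(root_sequence) if isinstance(root_sequence, str) \
        else np.asarray(root_sequence, dtype=np.uint8)
    if np.any(states > 3):
        raise ValueError("root sequence must be pure ACGT")

    leaves = {}
    stack = [(tree.root, states)]
    while stack:
        node, seq = stack.pop()
        if node.is_leaf:
            leaves[node.label] = decode(seq)
        for child in node.children:
            if child.length < 0:
                raise ValueError("negative branch length")
            P = model.transition_matrix(child.length)
            stack.append((child, _evolve_along_branch(seq, P, rng)))
    return SimulatedAlignment(sequences=leaves, length=len(states),
                              replicate_id=replicate_id, scenario_id=scenario_id)


def replicate_seed(master_seed: int, scenario_id: str, replicate_id: int) -> np.random.SeedSequence:
    """Deterministic per-(scenario, replicate) substream of the master seed."""
    tag = sum(ord(c) * 131 ** i for i, c in enumerate(scenario_id)) % (2 ** 31)
    return np.random.SeedSequence(entropy=master_seed,
                                  spawn_key=(tag, replicate_id))


def run_scenario_batch(per_scenario_trees: dict, model: SubstitutionModel,
                       n_replicates: int = 100, length: int = 3000,
                       seed: int = 0,
                       frequencies=(0.25, 0.25, 0.25, 0.25)) -> dict:
    """Independent replicates for each scenario-transformed tree.

    ``per_scenario_trees`` maps scenario_id -> substitutions-unit tree.
    Each replicate draws a fresh random root sequence; seeds derive
    deterministically from (seed, scenario_id, replicate_id).
    Returns scenario_id -> list of :class:`SimulatedAlignment`.
    """
    if not per_scenario_trees:
        raise ValueError("scenario grid is empty")
    out = {}
    for scenario_id, tree in per_scenario_trees.items():
        reps = []
        for r in range(n_replicates):
            rng = np.random.default_rng(replicate_seed(seed, scenario_id, r))
            root = simulate_root_sequence(length, frequencies, rng)
            aln = evolve(tree, model, root, rng,
                         replicate_id=r, scenario_id=scenario_id)
            reps.append(aln)
        out[scenario_id] = reps
    return out
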