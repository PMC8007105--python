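"""Coevolutionary contact potentials.

Two ingredients are combined here. A knowledge-based *statistical potential*
ε(σ,τ) = −log f(σ,τ) is computed from side-chain contact frequencies over a
set of structures. A family *Potts model* — site fields h_I(σ) and a pair
coupling tensor J_{I,K}(σ,τ) — is then fit to a projected alignment by
maximizing the pseudolikelihood (the product over sites of each residue's
conditional probability given the rest of its sequence) under an l2
regularizer centered on ε rather than on zero:

    α · Σ_{I<K,σ,τ} (J_{I,K}(σ,τ) − ε(σ,τ))²  +  λ_h · Σ h²

Centering the penalty on the statistical potential injects prior knowledge
of residue-residue interactions where the alignment statistics are thin, and
removes the gauge degeneracy of the Potts parametrization, so the optimum is
unique. The fitted tensor is finally projected onto one or two concrete
sequences and normalized so that the scale of two-body interactions is 1.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from . import alphabet
from .alignment import MSA
from .cgmodel import CGChain, CGSystem


class ConvergenceError(RuntimeError):
    """Pseudolikelihood optimization did not reach the gradient tolerance."""

    def __init__(self, message: str, gradient_norm: float):
        super().__init__(message)
        self.gradient_norm = gradient_norm


# ---------------------------------------------------------------------------
# statistical potential

@dataclasses.dataclass
class ContactCounts:
    """Symmetric table of observed side-chain contacts by residue-type pair."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("counts must be symmetric")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclasses.dataclass
class StatPotential:
    """Pair energy ε(σ,τ) over residue types, in model energy units."""

    eps: np.ndarray

    def __post_init__(self) -> None:
        self.eps = np.asarray(self.eps, dtype=float)
        if not np.all(np.isfinite(self.eps)):
            raise ValueError("statistical potential must be finite everywhere")
        if not np.allclose(self.eps, self.eps.T):
            raise ValueError("statistical potential must be symmetric")

    @property
    def n_types(self) -> int:
        return self.eps.shape[0]


def statistical_potential(
    counts: ContactCounts,
    pseudocount: float = 1.0,
    quasichemical: bool = False,
) -> StatPotential:
    """ε(σ,τ) = −log f(σ,τ) from regularized contact frequencies.

    With ``quasichemical=True`` the frequency is divided by the product of
    marginal type frequencies, ε = −log[f(σ,τ)/(p(σ)p(τ))], the
    quasi-chemical normalization.
    """
    c = counts.counts + pseudocount
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero counts with zero pseudocount")
    f = c / total
    if quasichemical:
        p = f.sum(axis=1)
        f = f / np.outer(p, p)
    return StatPotential(-np.log(f))


def sidechain_contact_counts(
    structures: Sequence[CGChain | CGSystem],
    cutoff: float = 8.5,
    min_separation: int = 3,
    n_types: int = 20,
) -> ContactCounts:
    """Count side-chain bead contacts by residue-type pair.

    A contact is an unordered SC-SC pair within ``cutoff`` Å, with
    |i−j| ≥ ``min_separation`` along a chain (inter-chain pairs have no
    separation filter). Each contact increments both (σ,τ) and (τ,σ) so
    the table stays symmetric.
    """
    counts = np.zeros((n_types, n_types))
    for obj in structures:
        chains = obj.chains if isinstance(obj, CGSystem) else [obj]
        sc = [ch.sc_coords for ch in chains]
        types = [
            np.array([alphabet.aa_index(a) for a in ch.sequence]) for ch in chains
        ]
        for ci in range(len(chains)):
            for cj in range(ci, len(chains)):
                d = np.linalg.norm(
                    sc[ci][:, None, :] - sc[cj][None, :, :], axis=-1
                )
                ii, jj = np.nonzero(d <= cutoff)
                if ci == cj:
                    keep = jj - ii >= min_separation
                else:
                    keep = np.ones_like(ii, dtype=bool)
                for a, b in zip(types[ci][ii[keep]], types[cj][jj[keep]]):
                    counts[a, b] += 1
                    if a != b:
                        counts[b, a] += 1
    return ContactCounts(counts)


# ---------------------------------------------------------------------------
# Potts parameters

@dataclasses.dataclass
class PottsParameters:
    """Fields h (L×q) and couplings J (L×L×q×q) of a family Potts model.

    J is stored as a full tensor satisfying J[I,I] = 0 and the pair
    symmetry J[I,K,a,b] == J[K,I,b,a]; the free parameters are the I<K
    blocks.
    """

    h: np.ndarray
    J: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError(f"J shape {self.J.shape} != ({L},{L},{q},{q})")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    @classmethod
    def zeros(cls, L: int, q: int) -> "PottsParameters":
        return cls(np.zeros((L, q)), np.zeros((L, L, q, q)))

    def frobenius_scores(self) -> np.ndarray:
        """L×L matrix of ‖J_{I,K}‖_F, the standard pair-coupling score."""
        return np.sqrt(np.einsum("ikab,ikab->ik", self.J, self.J))


def _pair_indices(L: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(L, k=1)


def _pack(params: PottsParameters) -> np.ndarray:
    iu, ku = _pair_indices(params.L)
    return np.concatenate([params.h.ravel(), params.J[iu, ku].ravel()])


def _unpack(x: np.ndarray, L: int, q: int) -> PottsParameters:
    h = x[: L * q].reshape(L, q)
    iu, ku = _pair_indices(L)
    Jpairs = x[L * q:].reshape(len(iu), q, q)
    J = np.zeros((L, L, q, q))
    J[iu, ku] = Jpairs
    J[ku, iu] = np.transpose(Jpairs, (0, 2, 1))
    return PottsParameters(h, J)


def _center_matrix(statpot: StatPotential | None, q: int) -> np.ndarray:
    """Regularizer center, extended by zeros to the gap state if needed."""
    if statpot is None:
        return np.zeros((q, q))
    eps = statpot.eps
    if eps.shape[0] == q:
        return eps
    if eps.shape[0] == q - 1:
        out = np.zeros((q, q))
        out[: q - 1, : q - 1] = eps
        return out
    raise ValueError(
        f"statistical potential has {eps.shape[0]} types; expected {q} or {q - 1}"
    )


def _plm_value_grad(
    x: np.ndarray,
    X: np.ndarray,
    L: int,
    q: int,
    center: np.ndarray,
    alpha: float,
    lambda_h: float,
) -> tuple[float, np.ndarray]:
    """Negative log-pseudolikelihood + regularizers, with exact gradient,
    over the packed free-parameter vector."""
    params = _unpack(x, L, q)
    h, J = params.h, params.J
    n = X.shape[0]

    onehot = np.zeros((n, L, q))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], X] = 1.0

    # logits[s, I, a] = h[I, a] + sum_K J[I, K, a, X[s, K]]
    logits = np.tile(h[None, :, :], (n, 1, 1))
    logits += np.einsum("ikab,skb->sia", J, onehot)

    logZ = logsumexp(logits, axis=2)
    picked = np.take_along_axis(logits, X[:, :, None], axis=2)[:, :, 0]
    nll = float(np.sum(logZ - picked))

    P = np.exp(logits - logZ[:, :, None]) - onehot  # d nll / d logits
    gh = P.sum(axis=0)
    G = np.einsum("sia,skb->ikab", P, onehot)  # site-I contribution to J[I,K]

    iu, ku = _pair_indices(L)
    # each free J_{I<K}(a,b) also appears in site K's conditional as J[K,I,b,a]
    gJ = G[iu, ku] + np.transpose(G[ku, iu], (0, 2, 1))

    value = nll
    if alpha > 0:
        dev = J[iu, ku] - center[None, :, :]
        value += alpha * float(np.sum(dev**2))
        gJ = gJ + 2.0 * alpha * dev
    if lambda_h > 0:
        value += lambda_h * float(np.sum(h**2))
        gh = gh + 2.0 * lambda_h * h

    return value, np.concatenate([gh.ravel(), gJ.ravel()])


def plm_objective(
    params: PottsParameters,
    msa: MSA | np.ndarray,
    statpot: StatPotential | None,
    alpha: float,
    lambda_h: float = 0.01,
) -> tuple[float, PottsParameters]:
    """Regularized negative log-pseudolikelihood and its exact gradient.

    The gradient is returned in parameter shape; its J part holds, for each
    I<K block, the derivative with respect to the free symmetric parameter
    (mirrored into the K>I block).
    """
    X = msa.encoded() if isinstance(msa, MSA) else np.asarray(msa)
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if X.ndim != 2 or X.shape[1] != params.L:
        raise ValueError(
            f"alignment width {X.shape} does not match L={params.L}"
        )
    if X.max() >= params.q:
        raise ValueError("alignment contains states outside the model alphabet")
    center = _center_matrix(statpot, params.q)
    value, g = _plm_value_grad(
        _pack(params), X, params.L, params.q, center, alpha, lambda_h
    )
    return value, _unpack(g, params.L, params.q)


def fit_plm(
    msa: MSA | np.ndarray,
    statpot: StatPotential | None = None,
    alpha: float = 1e-5,
    lambda_h: float = 0.01,
    gtol: float = 1e-4,
    max_iter: int = 2000,
    x0: np.ndarray | None = None,
) -> PottsParameters:
    """Fit the Potts model by regularized pseudolikelihood maximization.

    All L·q fields and the L(L-1)/2 symmetric coupling blocks are optimized
    jointly with L-BFGS; the informative regularizer makes the optimum
    unique, so the fit is gauge-stable.
    """
    X = msa.encoded() if isinstance(msa, MSA) else np.asarray(msa)
    if X.shape[0] < 2:
        raise ValueError("pseudolikelihood fitting needs at least 2 sequences")
    L = X.shape[1]
    q = alphabet.Q if isinstance(msa, MSA) else int(X.max()) + 1
    if isinstance(msa, MSA):
        q = max(q, int(X.max()) + 1)
    center = _center_matrix(statpot, q)

    n_free = L * q + (L * (L - 1) // 2) * q * q
    if x0 is None:
        x0 = np.zeros(n_free)

    res = minimize(
        _plm_value_grad,
        x0,
        args=(X, L, q, center, alpha, lambda_h),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 10 * max_iter,
                 "gtol": gtol, "ftol": 1e-14},
    )
    gnorm = float(np.max(np.abs(res.jac)))
    if not res.success and gnorm > gtol:
        raise ConvergenceError(
            f"pseudolikelihood fit did not converge: {res.message}", gnorm
        )
    return _unpack(res.x, L, q)


# ---------------------------------------------------------------------------
# projection onto target sequences

@dataclasses.dataclass
class CouplingMatrix:
    """Couplings evaluated at two concrete sequences: Jmat[i,j] =
    J_{i,j}(σ_i^A, σ_j^B). ``scale`` records the normalization divisor."""

    Jmat: np.ndarray
    scale: float = 1.0
    seq_a: str | None = None
    seq_b: str | None = None

    def __post_init__(self) -> None:
        self.Jmat = np.asarray(self.Jmat, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.Jmat.shape


def _encode_target(seq: str | np.ndarray, q: int) -> np.ndarray:
    if isinstance(seq, str):
        enc = alphabet.encode(seq).astype(int)
    else:
        enc = np.asarray(seq, dtype=int)
    if enc.max() >= q:
        raise ValueError("target sequence uses states outside the model alphabet")
    return enc


def project_couplings(
    params: PottsParameters,
    seq_a: str | np.ndarray,
    seq_b: str | np.ndarray | None = None,
) -> CouplingMatrix:
    """Evaluate the family tensor at one or two target sequences.

    With ``seq_b`` omitted (or equal to ``seq_a``) this is the cis /
    homophilic-trans matrix — identical by construction, the trans
    interaction between identical chains reuses the cis parameters. A
    different ``seq_b`` gives the heterophilic trans matrix through the
    shared family position numbering.
    """
    a = _encode_target(seq_a, params.q)
    homophilic = seq_b is None
    b = a if homophilic else _encode_target(seq_b, params.q)
    if len(a) != params.L or len(b) != params.L:
        raise ValueError(
            f"target length ({len(a)}, {len(b)}) != model L={params.L}"
        )
    ii, jj = np.meshgrid(np.arange(params.L), np.arange(params.L), indexing="ij")
    Jmat = params.J[ii, jj, a[ii], b[jj]]
    return CouplingMatrix(
        Jmat,
        seq_a=seq_a if isinstance(seq_a, str) else None,
        seq_b=(seq_a if isinstance(seq_a, str) else None) if homophilic
        else (seq_b if isinstance(seq_b, str) else None),
    )


def normalize_couplings(cm: CouplingMatrix) -> CouplingMatrix:
    """Divide by the RMS of the off-diagonal elements (two-body scale = 1)."""
    J = cm.Jmat
    off = ~np.eye(J.shape[0], J.shape[1], dtype=bool)
    rms = float(np.sqrt(np.mean(J[off] ** 2)))
    if rms == 0.0:
        raise ValueError("cannot normalize an all-zero coupling matrix")
    return CouplingMatrix(J / rms, scale=cm.scale * rms, seq_a=cm.seq_a, seq_b=cm.seq_b)


# ---------------------------------------------------------------------------
# plain-text 20x20 potential I/O

def write_potential(statpot: StatPotential, path) -> None:
    """Write a potential as a whitespace table with residue headers."""
    n = statpot.n_types
    letters = alphabet.AMINO_ACIDS[:n]
    with open(path, "w") as fh:
        fh.write("# side-chain contact potential, -log f(sigma, tau)\n")
        fh.write("  " + " ".join(f"{c:>9s}" for c in letters) + "\n")
        for i, row in enumerate(statpot.eps):
            fh.write(
                letters[i] + " " + " ".join(f"{v:9.5f}" for v in row) + "\n"
            )


def read_potential(path) -> StatPotential:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) >= 2 and _is_float(parts[1]):
                rows.append([float(v) for v in parts[1:]])
    return StatPotential(np.array(rows))


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def default_statistical_potential() -> StatPotential:
    """The packaged 20×20 potential.

    Computed once from this package's own synthetic toy structures (see
    ``data/synthetic_contact_potential.txt``); it is a stand-in with the
    right algebraic properties, not a PDB-derived table.
    """
    from importlib.resources import files

    path = files("coevomc").joinpath("data/synthetic_contact_potential.txt")
    return read_potential(path)
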