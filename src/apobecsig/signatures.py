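"""Signature refitting and de novo extraction.

Refitting follows the iterative scheme popularized by per-sample refitting
tools: starting from zero exposure, one signature weight at a time is
optimized by golden-section search on the squared reconstruction error of
the normalized catalog, the best single-coordinate move is applied, and
the loop repeats until no move helps; signatures ending below a 6% share
are discarded and the fit repeated until stable.

De novo extraction is non-negative matrix factorization minimizing the
generalized Kullback-Leibler divergence by multiplicative updates, best of
``n_restarts`` seeded restarts; extracted signatures are matched to a
reference set by cosine similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectrum import SBS96_CHANNELS, SbsCatalog, channel_index, parse_channel

DEFAULT_PRUNE_THRESHOLD = 0.06
_GOLDEN = (np.sqrt(5) - 1) / 2
_EPS = np.finfo(float).tiny


@dataclass
class SignatureSet:
    """Named 96-row column-stochastic signature matrix."""

    names: list[str]
    matrix: np.ndarray  # 96 x K

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 96:
            raise ValueError("signature matrix must be 96 x K")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("signature names do not match matrix columns")
        if (self.matrix < 0).any():
            raise ValueError("signature entries must be nonnegative")
        sums = self.matrix.sum(axis=0)
        if (sums <= 0).any():
            raise ValueError("signature with zero column")
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("signature columns must sum to 1 (± 1e-9)")

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def subset(self, names: list[str]) -> "SignatureSet":
        cols = [self.names.index(n) for n in names]
        return SignatureSet(list(names), self.matrix[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(SBS96_CHANNELS), columns=self.names)


def read_signature_tsv(path) -> SignatureSet:
    """Read a 96-row COSMIC-layout TSV (first column channel labels)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(SBS96_CHANNELS):
        raise ValueError("signature TSV is not in canonical COSMIC channel order")
    return SignatureSet(list(frame.columns), frame.to_numpy())


def write_signature_tsv(signatures: SignatureSet, path) -> None:
    signatures.to_frame().to_csv(path, sep="\t", index_label="channel")


@dataclass
class ExposureVector:
    """Per-sample signature contribution fractions (of explained mass)."""

    sample_id: str
    weights: dict[str, float]
    unexplained: float = 0.0

    def __post_init__(self):
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("exposure weights must be nonnegative")
        if sum(self.weights.values()) > 1 + 1e-9:
            raise ValueError("exposure weights exceed 1")

    def fraction(self, name: str) -> float:
        return self.weights.get(name, 0.0)


def sbs2_percentage(exposure: ExposureVector, name: str = "SBS2") -> float:
    """Refit exposure of the APOBEC C>T signature, in percent."""
    return 100.0 * exposure.fraction(name)


def cosine_similarity(a, b) -> float:
    """dot(a, b) / (|a| |b|) for nonnegative spectra."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def _golden_section(fun, lo: float, hi: float, tol: float = 1e-12) -> float:
    """Minimize a unimodal scalar function on [lo, hi]."""
    x1 = hi - _GOLDEN * (hi - lo)
    x2 = lo + _GOLDEN * (hi - lo)
    f1, f2 = fun(x1), fun(x2)
    while hi - lo > tol:
        if f1 <= f2:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - _GOLDEN * (hi - lo)
            f1 = fun(x1)
        else:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + _GOLDEN * (hi - lo)
            f2 = fun(x2)
    return (lo + hi) / 2


def _fit_weights(target: np.ndarray, matrix: np.ndarray,
                 tol: float = 1e-15, max_sweeps: int = 1000) -> np.ndarray:
    """Greedy coordinate descent with golden-section line searches."""
    k = matrix.shape[1]
    w = np.zeros(k)
    resid = target - matrix @ w
    err = float(resid @ resid)
    for _ in range(max_sweeps):
        best = (0.0, None, None)  # (improvement, index, new weight)
        for j in range(k):
            col = matrix[:, j]
            base = resid + w[j] * col

            def f(x, base=base, col=col):
                d = base - x * col
                return float(d @ d)

            x = _golden_section(f, 0.0, 1.0)
            gain = err - f(x)
            if gain > best[0]:
                best = (gain, j, x)
        if best[1] is None or best[0] < tol:
            break
        _, j, x = best
        resid = resid + (w[j] - x) * matrix[:, j]
        w[j] = x
        err = float(resid @ resid)
    return w


def refit_exposures(
    catalog: SbsCatalog,
    refs: SignatureSet,
    prune_threshold: float = DEFAULT_PRUNE_THRESHOLD,
) -> ExposureVector:
    """Refit a catalog against reference signatures.

    The catalog is normalized to channel frequencies; weights are fit by
    iterative golden-section coordinate descent on squared error, then any
    signature holding less than ``prune_threshold`` of the fitted mass is
    zeroed and the fit repeated on the survivors until stable.  Reported
    weights are fractions of the explained mass; ``unexplained`` is the
    mass the surviving signatures do not account for.
    """
    if catalog.total == 0:
        raise ValueError("cannot refit an empty catalog")
    target = catalog.frequencies()
    active = list(range(refs.k))
    while True:
        w_active = _fit_weights(target, refs.matrix[:, active])
        total = w_active.sum()
        if total == 0:
            break
        keep = [i for i, wi in zip(active, w_active) if wi / total >= prune_threshold]
        if keep == active:
            break
        active = keep
        if not active:
            break
    weights = {}
    unexplained = 1.0
    if active:
        w_active = _fit_weights(target, refs.matrix[:, active])
        total = w_active.sum()
        if total > 0:
            weights = {refs.names[i]: float(wi / total)
                       for i, wi in zip(active, w_active) if wi > 0}
            unexplained = float(max(0.0, 1.0 - total))
    return ExposureVector(catalog.sample_id, weights, unexplained)


# ---------------------------------------------------------------------------
# De novo extraction (KL-divergence multiplicative-update NMF)
# ---------------------------------------------------------------------------

def generalized_kl(V: np.ndarray, WH: np.ndarray) -> float:
    """D(V || WH) = sum V log(V/WH) - V + WH, with 0 log 0 = 0."""
    mask = V > 0
    div = float(np.sum(WH) - np.sum(V))
    div += float(np.sum(V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS))))
    return div


def _mu_kl(V, W, H, max_iter: int = 2000, tol: float = 1e-8):
    """Multiplicative updates for KL-NMF; returns (W, H, divergence history)."""
    history = [generalized_kl(V, W @ H + _EPS)]
    for it in range(max_iter):
        WH = W @ H + _EPS
        W *= (V / WH) @ H.T / np.maximum(H.sum(axis=1), _EPS)
        WH = W @ H + _EPS
        H *= W.T @ (V / WH) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        if (it + 1) % 10 == 0 or it == max_iter - 1:
            d = generalized_kl(V, W @ H + _EPS)
            history.append(d)
            if history[-2] - d < tol * max(1.0, abs(history[-2])):
                break
    return W, H, history


def extract_denovo(
    catalog_matrix,
    rank: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-8,
    names: list[str] | None = None,
) -> tuple[SignatureSet, np.ndarray]:
    """Extract ``rank`` de novo signatures from a 96 x S count matrix.

    Runs ``n_restarts`` seeded random initializations of KL multiplicative
    updates and keeps the factorization with the lowest final divergence.
    Signature columns are normalized to sum 1, with exposures (rank x S)
    rescaled compensatingly.  Deterministic for a fixed seed.
    """
    V = np.asarray(catalog_matrix, dtype=float)
    if V.ndim != 2 or V.shape[0] != 96:
        raise ValueError("catalog matrix must be 96 x S")
    S = V.shape[1]
    if not 1 <= rank <= S:
        raise ValueError(f"rank must lie in [1, {S}]")
    if (V < 0).any():
        raise ValueError("catalog matrix must be nonnegative")
    if (V.sum(axis=0) == 0).any():
        raise ValueError("all-zero sample column")

    scale = V.mean()
    best = None
    rng = np.random.default_rng(seed)
    for _ in range(max(1, n_restarts)):
        W0 = rng.uniform(0.5, 1.5, size=(96, rank)) * np.sqrt(scale / rank)
        H0 = rng.uniform(0.5, 1.5, size=(rank, S)) * np.sqrt(scale / rank)
        W, H, history = _mu_kl(V, W0, H0, max_iter=max_iter, tol=tol)
        if best is None or history[-1] < best[2]:
            best = (W, H, history[-1])
    W, H, _ = best
    col_sums = W.sum(axis=0)
    W = W / col_sums
    H = H * col_sums[:, None]
    sig_names = names or [f"Sig{chr(ord('A') + i)}" for i in range(rank)]
    return SignatureSet(sig_names, W), H


def match_to_reference(
    denovo: SignatureSet, refs: SignatureSet
) -> dict[str, tuple[str, float]]:
    """Best cosine match in ``refs`` for each de novo signature.

    Matching never fails: a poorly matching signature is reported with its
    (low) similarity.  Exact ties break toward the earlier reference.
    """
    matches = {}
    for i, name in enumerate(denovo.names):
        sims = [cosine_similarity(denovo.matrix[:, i], refs.matrix[:, j])
                for j in range(refs.k)]
        best = int(np.argmax(sims))
        matches[name] = (refs.names[best], float(sims[best]))
    return matches


# ---------------------------------------------------------------------------
# Synthetic reference set
# ---------------------------------------------------------------------------

def synthetic_reference_signatures(seed: int = 1202, k: int = 30) -> SignatureSet:
    """A synthetic stand-in for a COSMIC-style SBS1-SBS30 reference matrix.

    The three signatures the analyses lean on are biologically shaped:
    SBS2 concentrates C>T mass in the APOBEC-preferred TCN contexts (TCA
    and TCT above all), SBS1 concentrates C>T in NCG contexts (deamination
    of methyl-C), and SBS5 — the flat "aging" background — is the uniform
    96-vector.  The remaining columns are sparse random spectra, fixed by
    ``seed``, that keep refitting honest without mimicking any published
    signature.  Swap in a real matrix via :func:`read_signature_tsv`.
    """
    rng = np.random.default_rng(seed)
    matrix = np.zeros((96, k))
    names = [f"SBS{i}" for i in range(1, k + 1)]

    def put(col, five, ref, alt, three, mass):
        matrix[channel_index(five, ref, alt, three), col] += mass

    # SBS1: C>T at NCG
    for five, mass in zip("ACGT", (0.22, 0.24, 0.26, 0.20)):
        put(0, five, "C", "T", "G", mass)
    matrix[:, 0] += 0.08 / 96  # faint uniform floor
    # SBS2: C>T at TCN, dominated by TCA / TCT
    for three, mass in zip("ACGT", (0.33, 0.17, 0.05, 0.35)):
        put(1, "T", "C", "T", three, mass)
    matrix[:, 1] += 0.10 / 96
    # SBS5: uniform flat background
    matrix[:, 4] = 1.0 / 96
    # SBS13-like companion (C>G at TCN) for completeness of the APOBEC pair
    for three, mass in zip("ACGT", (0.30, 0.20, 0.08, 0.32)):
        put(12, "T", "C", "G", three, mass)
    matrix[:, 12] += 0.10 / 96
    # remaining columns: sparse Dirichlet-style spectra
    for col in range(k):
        if matrix[:, col].sum() > 0:
            continue
        support = rng.choice(96, size=rng.integers(6, 16), replace=False)
        raw = rng.gamma(1.2, size=support.size)
        matrix[support, col] = raw / raw.sum() * 0.92
        matrix[:, col] += 0.08 / 96
    matrix /= matrix.sum(axis=0, keepdims=True)
    return SignatureSet(names, matrix)


def flat_signature() -> np.ndarray:
    """The uniform 96-channel background spectrum."""
    return np.full(96, 1.0 / 96)
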