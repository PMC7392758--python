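"""Neutral sequence evolution under a Kimura two-parameter model.

Pseudogene sequences evolve free of selection, so a simple two-parameter
model (transition/transversion ratio kappa) is sufficient to generate the
divergence structure the distance estimators downstream must recover.
Branch lengths are expected substitutions per site.

Disablements (stop gains, deletions, insertions) are modelled as separate
Poisson processes and logged with positions; by default indel events are
recorded without altering the sequence, keeping orthologous sequences
alignment-free across strains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
STOP_CODONS = ("TAA", "TAG", "TGA")
# A<->G and C<->T are the transitions.
_TRANSITION_PARTNER = np.array([2, 3, 0, 1])


def encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 255, dtype=np.uint8)
    for c, i in _CODE.items():
        codes[arr == ord(c)] = i
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"sequence contains non-ACGT character {bad!r}")
    return codes


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def k2p_transition_matrix(d: float, kappa: float = 2.0) -> np.ndarray:
    """4x4 base substitution probability matrix after d substitutions/site."""
    if d < 0:
        raise ValueError("branch length must be >= 0")
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (alpha + beta) * d)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    P = np.full((4, 4), p_tv)
    for i in range(4):
        P[i, i] = p_same
        P[i, _TRANSITION_PARTNER[i]] = p_ts
    return P


def expected_p_distance(d: float, kappa: float = 2.0) -> float:
    """Expected fraction of differing sites after d substitutions/site."""
    P = k2p_transition_matrix(d, kappa)
    return float(1.0 - P[0, 0])


def divergence_for_identity(identity_pct: float, kappa: float = 2.0) -> float:
    """Branch length whose expected percent identity equals ``identity_pct``."""
    if not 25.0 < identity_pct <= 100.0:
        raise ValueError("identity must be in (25, 100] for an invertible K2P distance")
    target_p = 1.0 - identity_pct / 100.0
    if target_p == 0.0:
        return 0.0
    return brentq(lambda d: expected_p_distance(d, kappa) - target_p, 0.0, 50.0, xtol=1e-12)


def evolve_codes(codes: np.ndarray, d: float, rng: np.random.Generator,
                 kappa: float = 2.0) -> np.ndarray:
    """Vectorised K2P evolution of an encoded sequence over branch length d."""
    if d == 0:
        return codes.copy()
    P = k2p_transition_matrix(d, kappa)
    cum = np.cumsum(P, axis=1)
    u = rng.random(codes.shape[0])
    out = np.empty_like(codes)
    for base in range(4):
        mask = codes == base
        if mask.any():
            out[mask] = np.searchsorted(cum[base], u[mask], side="right")
    return out.astype(np.uint8)


def p_distance(a: np.ndarray, b: np.ndarray) -> float:
    if a.shape != b.shape:
        raise ValueError("sequences differ in length")
    return float(np.mean(a != b))


def identity_pct(a: np.ndarray, b: np.ndarray) -> float:
    return 100.0 * (1.0 - p_distance(a, b))


@dataclass
class MutationParams:
    """Mutation-process parameters for :func:`evolve_sequence`.

    Disablement rates are per site per unit time; ``subst_rate`` converts the
    branch length (substitutions/site) back onto the time scale they share.
    """

    kappa: float = 2.0
    subst_rate: float = 0.1
    stop_gain_rate: float = 0.004
    deletion_rate: float = 0.002
    insertion_rate: float = 0.001
    apply_indels: bool = False


def sample_disablement_counts(length: int, time: float, params: MutationParams,
                              rng: np.random.Generator) -> dict:
    """Poisson counts of each disablement class over ``time`` time units."""
    return {
        "stop": int(rng.poisson(params.stop_gain_rate * length * time)),
        "deletion": int(rng.poisson(params.deletion_rate * length * time)),
        "insertion": int(rng.poisson(params.insertion_rate * length * time)),
    }


def evolve_sequence(seq: str, branch_length: float, params: MutationParams | None = None,
                    rng: np.random.Generator | int | None = None):
    """Evolve ``seq`` over ``branch_length`` expected substitutions per site.

    Returns (mutated sequence, disablement log).  The log is a list of
    ``{"type", "position", ...}`` events; stop gains overwrite a frame-0
    codon with a random stop codon, while deletion/insertion events alter
    the sequence only when ``params.apply_indels`` is set.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    if branch_length < 0:
        raise ValueError("branch length must be >= 0")
    params = params or MutationParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    codes = encode(seq)
    if branch_length == 0:
        return seq, []
    codes = evolve_codes(codes, branch_length, rng, kappa=params.kappa)
    time = branch_length / params.subst_rate
    counts = sample_disablement_counts(len(codes), time, params, rng)
    log = []
    n_codons = len(codes) // 3
    for _ in range(counts["stop"]):
        if n_codons == 0:
            break
        ci = int(rng.integers(n_codons))
        stop = STOP_CODONS[int(rng.integers(3))]
        codes[3 * ci:3 * ci + 3] = encode(stop)
        log.append({"type": "stop", "position": 3 * ci, "codon": stop})
    seq_out = decode(codes)
    for _ in range(counts["deletion"]):
        pos = int(rng.integers(len(seq_out)))
        span = int(rng.integers(1, 11))
        log.append({"type": "deletion", "position": pos, "length": span})
        if params.apply_indels and len(seq_out) > span:
            seq_out = seq_out[:pos] + seq_out[pos + span:]
    for _ in range(counts["insertion"]):
        pos = int(rng.integers(len(seq_out)))
        span = int(rng.integers(1, 11))
        ins = decode(rng.integers(0, 4, size=span).astype(np.uint8))
        log.append({"type": "insertion", "position": pos, "length": span})
        if params.apply_indels:
            seq_out = seq_out[:pos] + ins + seq_out[pos:]
    return seq_out, log
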