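"""Total pseudogene-complement estimation.

Automatic pseudogene calls scale with the depth of the protein-coding
transcript annotation used as pipeline input, which varies across strains.
The estimator corrects the raw per-strain counts with (i) a transcript
deflation factor D(i) = N(T,i)/N(T,ref), and (ii) a calibration correction
C measured on a strain expected to share the reference's true complement,
C = (N(P,cal)/N(P,ref)) / (N(T,cal)/N(T,ref)); the corrected total is
M(P,i) = N(P,i) / (D(i) * C).  Composing the three steps for the
calibration strain returns N(P,ref) exactly.
"""

from __future__ import annotations

import pandas as pd

from .records import EstimationInputs


def deflation_factor(n_t_i: int, n_t_ref: int) -> float:
    """Transcript deflation factor D(i) = N(T,i) / N(T,ref)."""
    if n_t_ref <= 0:
        raise ValueError("n_t_ref must be > 0")
    if n_t_i <= 0:
        raise ValueError("n_t_i must be > 0")
    return n_t_i / n_t_ref


def calibration_factor(n_p_cal: int, n_p_ref: int, n_t_cal: int, n_t_ref: int) -> float:
    """Calibration correction C = (N(P,cal)/N(P,ref)) / (N(T,cal)/N(T,ref))."""
    for name, v in (("n_p_cal", n_p_cal), ("n_p_ref", n_p_ref),
                    ("n_t_cal", n_t_cal), ("n_t_ref", n_t_ref)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    return (n_p_cal / n_p_ref) / (n_t_cal / n_t_ref)


def estimate_total(n_p_i: int, d_i: float, c: float) -> float:
    """Corrected total M(P,i) = N(P,i) / (D(i) * C)."""
    if d_i <= 0:
        raise ValueError("deflation factor must be > 0")
    if c <= 0:
        raise ValueError("calibration factor must be > 0")
    return n_p_i / (d_i * c)


def estimate_from_inputs(inputs: EstimationInputs) -> float:
    d = deflation_factor(inputs.n_t_i, inputs.n_t_ref)
    c = calibration_factor(inputs.n_p_cal, inputs.n_p_ref, inputs.n_t_cal, inputs.n_t_ref)
    return estimate_total(inputs.n_p_i, d, c)


def estimate_table(counts: pd.DataFrame, reference: str, calibration: str,
                   rounded: bool = False) -> pd.DataFrame:
    """Per-strain corrected totals from a (strain, n_transcripts_input,
    n_pseudogenes_auto) table.

    ``rounded`` applies round-half-to-even for presentation; estimates are
    otherwise reported as real numbers.
    """
    counts = counts.set_index("strain")
    for s in (reference, calibration):
        if s not in counts.index:
            raise ValueError(f"strain {s!r} missing from counts table")
    n_t_ref = int(counts.loc[reference, "n_transcripts_input"])
    n_p_ref = int(counts.loc[reference, "n_pseudogenes_auto"])
    c = calibration_factor(int(counts.loc[calibration, "n_pseudogenes_auto"]), n_p_ref,
                           int(counts.loc[calibration, "n_transcripts_input"]), n_t_ref)
    rows = []
    for strain, row in counts.iterrows():
        d = deflation_factor(int(row["n_transcripts_input"]), n_t_ref)
        m = estimate_total(int(row["n_pseudogenes_auto"]), d, c)
        rows.append((strain, d, c, round(m) if rounded else m))
    return pd.DataFrame(rows, columns=["strain", "deflation", "calibration", "estimated_total"])
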