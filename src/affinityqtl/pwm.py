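"""Position weight matrices (PWMs) as base-frequency matrices.

A PWM here is a 4 x W matrix of per-position base frequencies (rows in
A, C, G, T order, columns summing to 1).  Zero entries are permitted and
meaningful: no pseudocount is ever added, so a base with frequency zero
at some position forbids any binding-site placement that uses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

__all__ = ["PWM", "BASES", "BASE_INDEX", "read_pwms", "write_pwms"]


@dataclass(frozen=True)
class PWM:
    """One motif for one transcription factor.

    Parameters
    ----------
    tf : str
        Transcription factor the motif belongs to.  Several PWMs may
        share a TF; downstream affinity changes are median-pooled per TF.
    motif_id : str
        Unique identifier of this matrix.
    freqs : ndarray of shape (4, W)
        Per-position base frequencies, rows ordered A, C, G, T.
    """

    tf: str
    motif_id: str
    freqs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.ndim != 2 or freqs.shape[0] != 4:
            raise ValueError("PWM frequencies must be a 4 x W matrix")
        if freqs.shape[1] < 1:
            raise ValueError("PWM must have at least one column")
        if (freqs < 0).any() or (freqs > 1).any():
            raise ValueError("PWM frequencies must lie in [0, 1]")
        colsums = freqs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError(f"PWM columns must sum to 1; got {colsums}")
        object.__setattr__(self, "freqs", freqs)

    @property
    def width(self) -> int:
        return self.freqs.shape[1]

    def consensus(self) -> str:
        """Most frequent base at each column (ties broken A<C<G<T)."""
        return "".join(BASES[i] for i in self.freqs.argmax(axis=0))


def write_pwms(pwms: list[PWM], path) -> None:
    """Write motifs as plain 4-row frequency blocks.

    Format: one ``>tf<TAB>motif_id`` header per motif followed by four
    whitespace-separated rows (A, C, G, T).
    """
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.tf}\t{pwm.motif_id}\n")
            for row in pwm.freqs:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_pwms(path) -> list[PWM]:
    """Read motifs written by :func:`write_pwms`."""
    pwms: list[PWM] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected motif header at line {i + 1}")
        tf, motif_id = lines[i][1:].split("\t")
        rows = [np.fromstring(lines[i + 1 + r], sep=" ") for r in range(4)]
        pwms.append(PWM(tf=tf, motif_id=motif_id, freqs=np.vstack(rows)))
        i += 5
    return pwms
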