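"""Expression-level filtering and co-twin normalization.

These two steps precede all testing: probes must show a reliably high signal
(intensity >= 50 in at least half the samples, by default), and twin-pair
expression is collapsed to one obese/lean ratio per probe per pair, which
cancels the shared genetic background, sex and age of a monozygotic pair.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .types import ExpressionMatrix, PairRatioMatrix, TwinPairSet, ValidationError


def filter_by_expression(
    matrix: ExpressionMatrix, threshold: float = 50.0, min_fraction: float = 0.5
) -> ExpressionMatrix:
    """Keep probes with intensity >= ``threshold`` in >= ceil(min_fraction * n) samples.

    The "at least half" rule is inclusive: with 2 samples one qualifying value
    suffices. Sample set and probe order are preserved. Idempotent.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    if not 0 < min_fraction <= 1:
        raise ValidationError("min_fraction must be in (0, 1]")
    needed = math.ceil(min_fraction * matrix.n_samples)
    counts = (matrix.values >= threshold).sum(axis=1)
    keep = counts >= needed
    if not keep.any():
        warnings.warn("expression filter removed every probe", stacklevel=2)
    return matrix.select_probes(keep)


def cotwin_normalize(
    matrix: ExpressionMatrix, pairs: TwinPairSet, pseudocount: float = 0.0
) -> PairRatioMatrix:
    """Divide each obese twin's intensities by the lean co-twin's.

    ratio[g, p] = (obese[g, p] + pseudocount) / (lean[g, p] + pseudocount).
    Values above 1 mean higher expression in the obese twin. The default
    pseudocount of 0 errors on zero lean intensities, which indicate an
    upstream normalization problem rather than real signal.
    """
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    obese = matrix.sample_values(pairs.obese_ids) + pseudocount
    lean = matrix.sample_values(pairs.lean_ids) + pseudocount
    zero = lean <= 0
    if zero.any():
        i, j = np.argwhere(zero)[0]
        raise ValidationError(
            f"zero lean intensity for probe {matrix.probe_ids[i]!r}, pair "
            f"{pairs.pair_ids[j]!r}; set a positive pseudocount to proceed"
        )
    return PairRatioMatrix(list(matrix.probe_ids), list(pairs.pair_ids), obese / lean)
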