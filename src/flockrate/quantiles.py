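"""Shared empirical-quantile convention.

Tertile cut-offs for the efficiency score and the Tukey outlier fences
must use the same quantile estimator, otherwise scores and fences
disagree for values near the boundaries.  The default is linear
interpolation between order statistics; any numpy quantile method name
can be passed through instead.
"""

from __future__ import annotations

import numpy as np

DEFAULT_METHOD = "linear"


def quantile(values, q, method: str = DEFAULT_METHOD) -> float:
    """Empirical quantile of defined (non-NaN) values."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("quantile of an empty sample")
    return float(np.quantile(arr, q, method=method))
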