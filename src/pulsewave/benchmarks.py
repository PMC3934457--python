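"""Published clinical benchmark confusion matrices (worked examples).

A clinical evaluation of elastic-kernel pulse-waveform classifiers on a
2470-waveform five-pattern dataset (800 moderate, 550 slippery, 800
taut, 160 hollow, 160 unsmooth) published the pooled 10-fold
cross-validation confusion matrices of a Gaussian-TWED-kernel SVM and
of a Gaussian-ERP kernel difference-weighted k-NN (GERP-KDF) baseline,
along with per-class and total average error rates (AERs).  The
matrices are reproduced here as worked examples for the error-rate
bookkeeping in :mod:`pulsewave.evaluation`.

Note: as printed, a few rows are internally inconsistent with the
declared class totals (the GTWED-SVM slippery row sums to 551 and its
unsmooth row to 161; the GERP-KDF hollow row sums to 159).  The printed
per-class AERs for those rows are consistent with the *declared* class
totals, which is why ``aer_from_confusion`` accepts a ``class_totals``
override.  The report renderer documents this caveat.

Rows are actual classes, columns predicted classes, both in
``CLASS_ORDER`` (moderate, slippery, taut, hollow, unsmooth).
"""

from __future__ import annotations

import numpy as np

#: Declared per-class sample counts of the benchmark dataset.
BENCHMARK_CLASS_TOTALS: tuple[int, ...] = (800, 550, 800, 160, 160)

#: Pooled confusion matrix of the Gaussian-TWED-kernel SVM
#: (operating point lam=1e-2, nu=0.25, sigma=1e2, C=1e2).
GTWED_SVM_CONFUSION = np.array(
    [
        [719, 63, 17, 1, 0],
        [74, 466, 4, 7, 0],
        [16, 3, 775, 1, 5],
        [7, 12, 3, 136, 2],
        [1, 1, 16, 2, 141],
    ],
    dtype=int,
)

#: Pooled confusion matrix of the GERP-KDF baseline
#: (k=30, eta=1e-2, sigma=10).
GERP_KDF_CONFUSION = np.array(
    [
        [710, 69, 18, 3, 0],
        [70, 465, 7, 8, 0],
        [23, 5, 762, 1, 10],
        [7, 10, 4, 136, 2],
        [1, 0, 21, 1, 137],
    ],
    dtype=int,
)
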