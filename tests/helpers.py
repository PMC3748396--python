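import numpy as np


def block_standard_error(trace, n_bins, n_blocks=20):
    """Per-bin Monte Carlo standard error of the empirical phase-difference
    density, estimated from disjoint trajectory blocks (robust to
    correlated samples)."""
    phi = trace.phase_difference()
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    width = 2 * np.pi / n_bins
    dens = np.array([np.histogram(b, bins=edges)[0] / (b.size * width)
                     for b in np.array_split(phi, n_blocks)])
    se = dens.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return np.maximum(se, 1e-4)
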