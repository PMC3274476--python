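"""Elementary stripe-pattern kernels shared by the simulator and the destriper."""

from __future__ import annotations

import math

import numpy as np


def stripe_kernel(
    sigma_along_um: float,
    sigma_across_um: float,
    voxel_size_um: tuple[float, float, float],
    sigma_z_um: float | None = None,
) -> np.ndarray:
    """Anisotropic Gaussian stripe pattern, long axis along x, unit L2 norm.

    Returns a 2D ``(y, x)`` kernel, or 3D ``(z, y, x)`` when
    ``sigma_z_um`` is given. Support is truncated at 4 sigma and always
    odd-sized, which keeps convolution and correlation exact adjoints.
    """
    if sigma_along_um <= 0 or sigma_across_um <= 0:
        raise ValueError("kernel sigmas must be positive")
    vx, vy, vz = voxel_size_um
    sigmas_vox = [sigma_across_um / vy, sigma_along_um / vx]
    if sigma_z_um is not None:
        sigmas_vox = [sigma_z_um / vz] + sigmas_vox
    axes = []
    for s in sigmas_vox:
        half = max(int(math.ceil(4 * s)), 1)
        ax = np.arange(-half, half + 1)
        axes.append(np.exp(-0.5 * (ax / s) ** 2))
    k = axes[0]
    for a in axes[1:]:
        k = np.multiply.outer(k, a)
    return k / np.linalg.norm(k)
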