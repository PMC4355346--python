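"""Eight-neighbour anisotropic (Perona--Malik) diffusion.

The optic disc is the brightest blob of the red channel; before it is
thresholded, the channel is smoothed with an explicit eight-direction
Perona--Malik scheme,

    I_{t+1} = I_t + psi * sum_dir C(grad_dir) * grad_dir,

where ``grad_dir = I(neighbour) - I(centre)`` for the eight compass
neighbours and the diffusivity ``C(g) = 1 / (1 + (g / kappa)**2)`` shuts
diffusion down across strong edges.  With ``psi <= 1/8`` the update is a
convex combination of the pixel and its neighbours, so the scheme obeys a
discrete maximum principle: values never leave the input range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import FormatError

#: (row, col) offset of the +1 cell for each compass direction.
OFFSETS = {
    "N": (-1, 0),
    "S": (1, 0),
    "E": (0, 1),
    "W": (0, -1),
    "NE": (-1, 1),
    "NW": (-1, -1),
    "SE": (1, 1),
    "SW": (1, -1),
}

#: The eight 3x3 difference templates, written row-major with ``-1`` at the
#: centre and a single ``+1`` at the neighbour position.
TEMPLATE_CODES = {
    "N": "0100-10000",
    "S": "0000-10010",
    "E": "0000-11000",
    "W": "0001-10000",
    "NE": "0010-10000",
    "SE": "0000-10001",
    "SW": "0000-10100",
    "NW": "1000-10000",
}


@dataclass(frozen=True)
class DiffusionParams:
    """Parameters of the explicit diffusion scheme.

    psi
        Update rate in (0, 1]; 1/8 keeps the eight-neighbour update a
        convex-bounded perturbation (stability of the explicit scheme).
    kappa
        Edge-sensitivity scale in grey levels; gradients well below it are
        smoothed, gradients above it are preserved.
    iterations
        Number of explicit time steps.
    """

    psi: float = 0.125
    kappa: float = 30.0
    iterations: int = 15

    def __post_init__(self):
        if not 0.0 < self.psi <= 1.0:
            raise ValueError(f"psi must lie in (0, 1], got {self.psi}")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        if int(self.iterations) != self.iterations or self.iterations < 1:
            raise ValueError(f"iterations must be a positive integer, got {self.iterations}")


@dataclass(frozen=True, eq=False)
class DirectionalKernel:
    """A 3x3 neighbour-minus-centre difference mask for one direction."""

    direction: str
    weights: np.ndarray  # 3x3 int array: centre -1, one +1, rest 0


def decode_kernel(code: str) -> DirectionalKernel:
    """Decode a 9-entry row-major template string such as ``"0100-10000"``.

    Entries are the digits 0 and 1 plus the two-character token ``-1``.
    The decoded mask must sum to zero, carry ``-1`` at the centre and a
    single ``+1`` elsewhere; anything else raises :class:`FormatError`.
    """
    entries = []
    i = 0
    while i < len(code):
        if code[i] == "-":
            if i + 1 >= len(code) or code[i + 1] != "1":
                raise FormatError(f"cannot decode template {code!r}: dangling '-'")
            entries.append(-1)
            i += 2
        elif code[i] in "01":
            entries.append(int(code[i]))
            i += 1
        else:
            raise FormatError(f"cannot decode template {code!r}: bad character {code[i]!r}")
    if len(entries) != 9:
        raise FormatError(f"template {code!r} decodes to {len(entries)} entries, expected 9")
    weights = np.array(entries, dtype=int).reshape(3, 3)
    if weights.sum() != 0 or weights[1, 1] != -1 or np.count_nonzero(weights == 1) != 1:
        raise FormatError(f"template {code!r} is not a centre -1 / single +1 difference mask")
    r, c = (int(v) for v in np.argwhere(weights == 1)[0])
    direction = {v: k for k, v in OFFSETS.items()}[(r - 1, c - 1)]
    return DirectionalKernel(direction=direction, weights=weights)


def kernels() -> dict[str, DirectionalKernel]:
    """All eight directional kernels, keyed by compass direction."""
    return {d: decode_kernel(code) for d, code in TEMPLATE_CODES.items()}


def directional_gradient(image: np.ndarray, kernel: DirectionalKernel) -> np.ndarray:
    """Per-pixel neighbour-minus-centre difference for one direction.

    Borders are edge-replicated, so gradients across the image frame are
    zero and the output has the input's shape.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError(f"image must be 2-D and at least 3x3, got shape {image.shape}")
    return ndimage.correlate(image, kernel.weights.astype(float), mode="nearest")


def kappa_coefficient(grad, kappa: float):
    """Diffusivity ``1 / (1 + (grad / kappa)**2)``, in (0, 1].

    Equals 1 exactly when ``grad`` is 0 and 1/2 when ``|grad| == kappa``.
    Accepts scalars or arrays.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    grad = np.asarray(grad, dtype=float)
    out = 1.0 / (1.0 + (grad / kappa) ** 2)
    return float(out) if out.ndim == 0 else out


def diffuse(image: np.ndarray, params: DiffusionParams | None = None) -> np.ndarray:
    """Run the explicit eight-direction diffusion scheme.

    Returns a float array of the input's shape.  Constant images are exact
    fixed points (all gradients vanish).  All arithmetic is double
    precision; quantisation back to 8 bits happens only at image export.
    """
    params = params or DiffusionParams()
    out = np.array(image, dtype=float, copy=True)
    if out.ndim != 2 or min(out.shape) < 3:
        raise ValueError(f"image must be 2-D and at least 3x3, got shape {out.shape}")
    h, w = out.shape
    kappa = params.kappa
    for _ in range(params.iterations):
        padded = np.pad(out, 1, mode="edge")
        flux = np.zeros_like(out)
        for dr, dc in OFFSETS.values():
            grad = padded[1 + dr : 1 + dr + h, 1 + dc : 1 + dc + w] - out
            flux += grad / (1.0 + (grad / kappa) ** 2)
        out += params.psi * flux
    return out
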