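"""The TanhExp activation, f(x) = x * tanh(exp(x)).

TanhExp is a smooth, non-monotonic activation with a bounded negative lobe
(minimum ~ -0.353) and a positive part that hugs the identity: for x >= 1
the deviation |f(x) - x| never exceeds 0.01, so deep stacks behave almost
like linear maps on positive activations while keeping a useful gradient
near zero.  It is used after every convolution in the detector except the
linear bottleneck projections.

Naive evaluation overflows for x beyond ~709 because of exp(x); since
tanh(exp(x)) is already 1.0 to double precision for x > ~20, the large-x
branch returns x unchanged.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .nn import Module

# exp(20) ~ 4.85e8; tanh of that is 1.0 to well below double-precision ulp
_LINEAR_CUTOFF = 20.0


def tanhexp(x):
    """Elementwise x * tanh(exp(x)) on scalars or arrays.

    Preserves the input's floating dtype; non-finite inputs propagate
    (no clamping).  Safe against exp overflow for arbitrarily large x.
    """
    arr = np.asarray(x)
    if arr.dtype.kind in "iub":
        arr = arr.astype(np.float64)
    safe = np.minimum(arr, _LINEAR_CUTOFF)
    out = np.where(arr > _LINEAR_CUTOFF, arr, arr * np.tanh(np.exp(safe)))
    if np.isscalar(x) or np.ndim(x) == 0:
        return out.item() if isinstance(x, (int, float)) else out[()]
    return out


def tanhexp_t(x):
    """TanhExp on autodiff tensors, with the analytic derivative.

    f'(x) = tanh(e^x) + x e^x (1 - tanh^2(e^x)); for x above the linear
    cutoff both f and f' are the identity's to machine precision.
    """
    x = ad.as_tensor(x)
    xd = x.data
    safe_e = np.exp(np.minimum(xd, _LINEAR_CUTOFF))
    t = np.tanh(safe_e)
    big = xd > _LINEAR_CUTOFF
    out = np.where(big, xd, xd * t)

    def vjp(go):
        d = t + xd * safe_e * (1.0 - t * t)
        return (go * np.where(big, 1.0, d).astype(xd.dtype, copy=False),)

    return ad._make(out, (x,), vjp)


class TanhExp(Module):
    """Module wrapper so TanhExp can sit inside Sequential stacks."""

    def forward(self, x):
        return tanhexp_t(x)


class Identity(Module):
    def forward(self, x):
        return x
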