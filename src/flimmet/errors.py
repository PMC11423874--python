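"""Exception hierarchy for flimmet.

All exceptions derive from :class:`FlimError` so callers can catch the
package's failures with a single ``except`` clause while still
distinguishing validation problems from degenerate statistics or I/O.
"""


class FlimError(Exception):
    """Base class for all flimmet errors."""


class ValidationError(FlimError, ValueError):
    """Input violates a documented precondition or type invariant."""


class UndefinedLifetimeError(FlimError, ValueError):
    """Amplitude-weighted lifetime undefined (total amplitude is zero)."""


class UndefinedRatioError(FlimError, ValueError):
    """Optical redox ratio undefined (NAD(P)H intensity is not positive)."""


class InsufficientSignalError(FlimError, ValueError):
    """Histogram holds too few photons to attempt a decay fit."""


class DegenerateDofError(FlimError, ValueError):
    """Goodness-of-fit has no degrees of freedom left."""


class DegenerateTestError(FlimError, ValueError):
    """Paired test cannot be computed (all differences zero / zero spread)."""


class InsufficientPairsError(FlimError, ValueError):
    """Fewer donor pairs than the minimum the paired test requires."""


class SceneError(FlimError, ValueError):
    """Synthetic scene cannot be realised (e.g. infeasible cell packing)."""


class FormatError(FlimError, ValueError):
    """File content does not match the expected on-disk format."""
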