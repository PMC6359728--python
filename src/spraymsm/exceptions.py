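"""Exception hierarchy for spraymsm.

All errors derive from :class:`SprayMSMError` so callers can catch the
package's failures with a single except clause; the subclasses also derive
from ``ValueError`` because they signal invalid caller input.
"""


class SprayMSMError(Exception):
    """Base class for all spraymsm errors."""


class InvalidParameterError(SprayMSMError, ValueError):
    """A configuration parameter is outside its valid range."""


class InvalidInputError(SprayMSMError, ValueError):
    """A data input violates a precondition (shape, emptiness, labels)."""


class DegenerateDataError(SprayMSMError, ValueError):
    """The data carry no usable signal (e.g. a zero autocorrelation matrix)."""


class EmptyStreamError(SprayMSMError, ValueError):
    """A frame source decoded to zero frames."""


class UndefinedMetricError(SprayMSMError, ValueError):
    """A metric is requested on an empty tally (zero total count)."""
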