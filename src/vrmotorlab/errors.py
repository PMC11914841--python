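"""Exception hierarchy shared across the package.

All exceptions derive from :class:`VRMotorLabError` so callers can catch
package failures with a single ``except`` clause while still distinguishing
malformed files (:class:`FormatError`), internally inconsistent data
(:class:`IntegrityError`) and invalid arguments (:class:`ParameterError`).
"""


class VRMotorLabError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VRMotorLabError, ValueError):
    """An external file does not follow the expected dialect/schema."""


class IntegrityError(VRMotorLabError, ValueError):
    """Data parsed fine but violates a domain invariant."""


class ParameterError(VRMotorLabError, ValueError):
    """A function argument is outside its valid domain."""
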