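"""Exception hierarchy for clonesim.

Every error raised on a user-facing code path derives from
:class:`CloneSimError`, so callers (and the CLI) can distinguish
simulation outcomes from programming errors.
"""


class CloneSimError(Exception):
    """Base class for all clonesim errors."""


class TopologyError(CloneSimError):
    """An operation was applied to a molecule of the wrong topology."""


class IncompatibleEndsError(CloneSimError):
    """Two DNA ends cannot be ligated (overhangs differ or mix blunt/sticky)."""


class UniqueSiteError(CloneSimError):
    """linearize() requires exactly one recognition site."""


class NoAmpliconError(CloneSimError):
    """PCR simulation found no productive primer pair."""


class AmbiguousProductError(CloneSimError):
    """PCR simulation found more than one productive primer pair.

    The offending products are attached as ``products``.
    """

    def __init__(self, message, products=()):
        super().__init__(message)
        self.products = list(products)


class DesignError(CloneSimError):
    """Primer design could not satisfy its constraints."""


class ParseError(CloneSimError):
    """A sequence file could not be parsed."""


class FetchError(CloneSimError):
    """A remote record could not be retrieved and is not cached."""
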