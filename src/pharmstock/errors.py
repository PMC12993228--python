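"""Exception hierarchy shared across the package.

All errors derive from :class:`PharmstockError` so callers can catch the
package's failures with a single ``except`` clause; the CLI maps the
subclasses onto distinct exit codes.
"""


class PharmstockError(Exception):
    """Base class for all pharmstock errors."""


class SchemaError(PharmstockError, ValueError):
    """A ledger file is missing a mandatory column or is otherwise malformed."""


class ValidationError(PharmstockError, ValueError):
    """A record or dataset violates a domain invariant (duplicate id, negative value...)."""


class EmptyInputError(PharmstockError, ValueError):
    """An operation received no items to work on."""


class DegenerateInputError(PharmstockError, ValueError):
    """Input is structurally valid but the operation is undefined on it
    (e.g. all amounts non-positive, zero average inventory balance)."""


class MissingLabelError(PharmstockError, KeyError):
    """A product lacks a class label on an axis required by a cross-tabulation."""
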