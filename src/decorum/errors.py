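"""Exception hierarchy.

Client faults (bad payloads, unknown media types, precondition violations)
and infrastructure faults (transport, registration) are kept distinct so the
service kernel can map them onto 400- vs 500-class HTTP statuses.
"""


class DecorumError(Exception):
    """Base class for all package errors."""


class UnsupportedMediaTypeError(DecorumError):
    """The Content-Type names an RDF serialization we do not speak."""


class GraphParseError(DecorumError):
    """The payload claimed to be RDF but did not parse."""


class OntologyError(DecorumError):
    """An ontology document could not be obtained or interpreted."""


class MissingClassError(OntologyError):
    """A restriction refers to a class that the ontology does not define."""


class DescriptionError(DecorumError):
    """A service-interface document violates the single-operation contract."""


class TransportError(DecorumError):
    """An endpoint could not be reached over the given transport."""


class InvocationError(DecorumError):
    """A client-side precondition for invoking a service failed."""


class RegistrationError(DecorumError):
    """A service could not be admitted to the registry."""


class AmbiguousParameterError(DecorumError):
    """More than one parameter node of the declared class was supplied."""


class UnsupportedFeatureError(DecorumError):
    """The query uses a SPARQL feature outside the supported subset."""
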