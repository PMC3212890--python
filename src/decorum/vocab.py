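"""Namespace constants.

Every IRI the stack emits or matches on lives here, bit-exact, so that wire
compatibility is adjusted in exactly one place.  ``MYGRID`` carries the
service-description vocabulary (the myGrid/Moby service ontology); ``SVC``
holds the handful of operational annotations this implementation adds
(asynchrony flag, per-root error diagnostics).
"""

from rdflib import Namespace
from rdflib.namespace import FOAF, OWL, RDF, RDFS, XSD  # noqa: F401  (re-exported)

#: myGrid/Moby service ontology terms used in service-interface documents.
MYGRID = Namespace("http://www.mygrid.org.uk/mygrid-moby-service#")

#: Operational annotations of this stack (async capability, diagnostics).
SVC = Namespace("http://decorum.example.org/vocab#")

# Service description vocabulary — the single table to edit for
# compatibility with historical interface documents.
SERVICE_DESCRIPTION = MYGRID.serviceDescription
HAS_OPERATION = MYGRID.hasOperation
INPUT_PARAMETER = MYGRID.inputParameter
OUTPUT_PARAMETER = MYGRID.outputParameter
SECONDARY_PARAMETER = MYGRID.secondaryParameter
OBJECT_TYPE = MYGRID.objectType
SERVICE_NAME_TEXT = MYGRID.hasServiceNameText
SERVICE_DESCRIPTION_TEXT = MYGRID.hasServiceDescriptionText
AUTHORITY = MYGRID.providedBy

ASYNC_CAPABLE = SVC.asynchronous
SERVICE_ERROR = SVC.serviceError

#: Accepted Content-Type values and their parser/serializer dialects.
MEDIA_RDFXML = "application/rdf+xml"
MEDIA_N3 = "text/rdf+n3"
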