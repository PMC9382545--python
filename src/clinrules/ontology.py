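"""Optional RDF/Turtle export of a knowledge base's concept layer.

Mirrors the concepts, their terminology annotations and the is-a
hierarchy as an RDF graph so the KB can be inspected with ontology
tooling.  The native YAML document remains the engine's source of
truth; no description-logic reasoning is performed over the export.
"""

from __future__ import annotations

from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef

from .knowledge import KnowledgeBase

__all__ = ["export_ontology"]

CR = Namespace("urn:clinrules:ontology#")


def export_ontology(kb: KnowledgeBase) -> str:
    """Serialize the concept layer of ``kb`` as Turtle."""
    g = Graph()
    g.bind("cr", CR)
    g.bind("rdfs", RDFS)

    for c in kb.concepts:
        node = URIRef(CR + c.id)
        g.add((node, RDF.type, CR.ClinicalConcept))
        g.add((node, RDFS.label, Literal(c.label)))
        g.add((node, CR.valueKind, Literal(c.value_kind.value)))
        if c.units is not None:
            g.add((node, CR.units, Literal(c.units)))
        if c.chronic:
            g.add((node, CR.chronic, Literal(True)))
        if c.snomed_annotation is not None:
            g.add((node, CR.snomedCode, Literal(c.snomed_annotation)))
        if c.fhir_annotation is not None:
            ann = c.fhir_annotation
            g.add((node, CR.fhirResourceType, Literal(ann.resource_type)))
            g.add((node, CR.fhirCodeSystem, Literal(ann.code_system)))
            g.add((node, CR.fhirCode, Literal(ann.code)))

    for link in kb.hierarchy:
        g.add((URIRef(CR + link.child_id), RDFS.subClassOf, URIRef(CR + link.parent_id)))

    return g.serialize(format="turtle")
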