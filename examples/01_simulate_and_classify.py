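"""Simulate a two-population transcriptome and classify splice events.

Builds a toy genome with 30 multi-exon genes, spawns novel isoforms by
applying labeled splice events to each canonical transcript, then scores
every isoform against the annotation and recovers the event labels.
"""

from collections import Counter

from isokit import (
    SimulationConfig,
    best_reference_match,
    classify_events,
    generate_genome_and_annotation,
    simulate_isoform_truth,
)

config = SimulationConfig(n_genes=30, seed=42)
genome, annotation = generate_genome_and_annotation(config)
truth = simulate_isoform_truth(annotation, config)

novel = [r for r in truth if r.is_novel]
scores = Counter()
recovered = 0
events_seen = Counter()
for rec in truth:
    match = best_reference_match(rec.isoform, annotation)
    scores[match.score] += 1
    if rec.is_novel:
        called = classify_events(rec.isoform, annotation.canonical(rec.gene_id))
        recovered += called.events == set(rec.true_events)
        events_seen.update(called.events)

print(f"genes: {len(annotation)}  isoforms: {len(truth)}  novel: {len(novel)}")
print(f"score histogram (0-5): {dict(sorted(scores.items()))}")
print(f"event labels called: {dict(sorted(events_seen.items()))}")
print(f"exact event-set recovery: {recovered}/{len(novel)}")
# Score 5 marks isoforms identical to annotation; scores 2-3 are novel
# isoforms with interpretable splicing. Recovery of n/n shows the classifier
# inverts the generator's event grammar exactly.
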