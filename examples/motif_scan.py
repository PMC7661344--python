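"""Scan promoter sequences for a degenerate consensus motif on both strands.

Uses the published consensus CCTC[AT][GC]CC[TA]CC[CT] and its looser
printed complement form; classifies three short sequences as exact,
partial, or no match -- the promoter-fragment triage that decides which
reporter constructs are worth building.
"""

from chipglyco import classify_sequence, parse_pattern, render_pattern, reverse_complement, scan

consensus = parse_pattern("CCTC[AT][GC]CC[TA]CC[CT]")
printed_rc = parse_pattern("[GA][GA][GC][AT]GG[CG]xxAGG")

print("strict reverse complement of the consensus:",
      render_pattern(reverse_complement(consensus)))

seq1 = "TTGGGCTG" + "GGCAGGCAAAGG" + "AAATCC"   # carries the bound motif
seq2 = "TATATATATATATATATATATATATA"             # nothing plausible
seq3 = "TTTTTT" + "GCCTCCA" + "TTTTTTTTTTT"     # a 7-bp partial agreement

for name, seq, panel in (
    ("Seq 1", seq1, [printed_rc]),
    ("Seq 2", seq2, [consensus, printed_rc]),
    ("Seq 3", seq3, [parse_pattern("GG[GA]CC[TA]CC[AT]GGG")]),
):
    verdict, best = classify_sequence(seq, panel, partial_min=7)
    where = f" at offset {best.offset} ({best.strand}), span {best.matched_span}" if best else ""
    print(f"{name}: {verdict}{where}")

hits = scan(seq1, printed_rc, both_strands=True)
print(f"full scan of Seq 1: {len(hits)} hit(s), first at offset {hits[0].offset}")
# EXACT means a full 12-position window satisfied the pattern; PARTIAL a
# contiguous run of >=7 positions; NONE nothing above that bar.
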