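"""Maximal repeat survey with the analytic expectation statistic.

Plants reverse and palindromic repeats into random genomes, finds every
maximal repeat pair, and prints a survey table with expectation values
E = (n²/2)·(1/4)^l·(3/4)² — the chance of seeing a maximal pair of that
length in a random sequence of the genome's size.  Also re-derives the
twelve reference E-values from their (n, l) pairs.
"""

from virrecruit import RepeatPlant, generate_ancestor, plant_repeats, repeat_report
from virrecruit.pipeline import run_verify_table2

genomes = []
for i, (length, plants) in enumerate([
    (5662, [RepeatPlant("reverse", 16, 300, 900),
            RepeatPlant("palindromic", 14, 4300, 4700)]),
    (863, [RepeatPlant("reverse", 13, 100, 400)]),
    (417, []),
]):
    g = generate_ancestor(length, 0.52, seed=20 + i, record_id=f"contig{i + 1}")
    genomes.append(plant_repeats(g, plants))

rows = repeat_report(genomes, min_len=13, evalue_max=0.1)
print("contig    type  length  start1  start2  E-value")
for cid, code, length, p1, p2, ev in rows:
    print(f"{cid:8s}  {code:4s}  {length:6d}  {p1 + 1:6d}  {p2 + 1:6d}  {ev:.2e}")
print("R = reverse repeat (reversed copy), P = palindromic (reverse complement).")
print("A small E-value means the repeat is unlikely to be a chance pair.")

print("\nAnalytic check against the twelve reference (n, l, E) rows:")
for n, l, computed, expected, ok in run_verify_table2():
    print(f"  n={n:5d} l={l:2d}  computed {computed:>8s}  expected {expected:>8s}"
          f"  {'pass' if ok else 'FAIL'}")
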