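"""Extract the randomized insert from reads of an N40 selection library.

Builds full-length constructs around three known candidate inserts, then
shows how the scanner validates flanks, enforces the 38-42 nt length window,
and rejects an over-long PCR by-product chimera.
"""

from selexpipe import LibraryDesign, find_flanks, reverse_complement

design = LibraryDesign()  # 18-nt constant flanks around a 40-nt random core
print(f"library design: {design.flank5}-N{design.n_length}-{design.flank3}")
print(f"theoretical amplicon: {design.amplicon_length} bp, "
      f"retained insert window: {design.length_window}\n")

candidates = {
    "SP1": "CACTCTCACCTTCCTGTCACTCCTTTTTTCACTCTCACTC",
    "SP2": "CACTCACTCTTTCCCTTATCTGCTCACTCTTCATTCACTC",
    "SP3": "CACCGTCCTTTTCTAGCATCTCTGTCACTCTTTCTCACTC",
}

for name, insert in candidates.items():
    read = design.wrap(insert)
    fwd = find_flanks(read, design)
    rev = find_flanks(reverse_complement(read), design)
    print(f"{name}: forward {fwd.status.value} ({fwd.insert_length} nt), "
          f"reverse-strand read {rev.status.value} "
          f"(orientation {rev.orientation})")

# A chimeric by-product: 50 random-region bases instead of ~40. The length
# window rejects it no matter where the flanks are placed.
byproduct = design.wrap(candidates["SP1"] + "ACGTACGTAC")
print(f"\n50-nt by-product insert: {find_flanks(byproduct, design).status.value}")
print("PASS means both constant regions were found with an in-window insert;")
print("LENGTH_FAIL marks the elongated PCR by-products the pipeline removes.")
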