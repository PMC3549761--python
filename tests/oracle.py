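"""Independent brute-force re-derivation of the final locus set.

Deliberately written from scratch against the documented rules: it
parses SAM text with its own minimal parser, tallies every position with
plain dictionaries, and evaluates each selection rule directly.  It
shares no code with the package modules it checks.
"""

import re
from collections import defaultdict

CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
ACGT = "ACGT"

BANDS = ((1, 5, 3), (6, 10, 2), (11, 20, 1))


def tally_sam(sam_path):
    """Return (base_counts, indel_evidence, ambig_evidence, aligned_bases).

    base_counts[(contig, pos)][individual][base] -> reads;
    indel/ambig are (contig, pos) -> int tallies.
    """
    base_counts = defaultdict(lambda: defaultdict(lambda: defaultdict(int)))
    indel = defaultdict(int)
    ambig = defaultdict(int)
    aligned_bases = 0
    contig_lengths = {}
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    fields = dict(f.split(":", 1) for f in line.split("\t")[1:])
                    contig_lengths[fields["SN"]] = int(fields["LN"].strip())
                continue
            fields = line.rstrip("\n").split("\t")
            flag = int(fields[1])
            if flag & 4:
                continue
            contig, pos, cigar, seq = fields[2], int(fields[3]) - 1, fields[5], fields[9]
            individual = None
            for tag in fields[11:]:
                if tag.startswith("RG:Z:"):
                    individual = tag[5:]
            if individual is None:
                individual = fields[0].split("|")[0]
            ref_pos, q_pos = pos, 0
            for n, op in CIGAR_RE.findall(cigar):
                n = int(n)
                if op in "M=X":
                    for k in range(n):
                        base = seq[q_pos + k].upper()
                        key = (contig, ref_pos + k)
                        if base in ACGT:
                            base_counts[key][individual][base] += 1
                        else:
                            base_counts[key][individual]["N"] += 1
                            ambig[key] += 1
                        aligned_bases += 1
                    ref_pos += n
                    q_pos += n
                elif op == "I":
                    if ref_pos > 0:
                        indel[(contig, ref_pos - 1)] += 1
                    if ref_pos < contig_lengths[contig]:
                        indel[(contig, ref_pos)] += 1
                    q_pos += n
                elif op in "DN":
                    for k in range(n):
                        indel[(contig, ref_pos + k)] += 1
                    ref_pos += n
                elif op == "S":
                    q_pos += n
    return base_counts, indel, ambig, aligned_bases


def parse_bed_masks(bed_path):
    intervals = defaultdict(list)
    mtdna = set()
    with open(bed_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 4 and parts[3] == "mtDNA":
                mtdna.add(parts[0])
            elif len(parts) >= 3:
                intervals[parts[0]].append((int(parts[1]), int(parts[2])))
    return intervals, mtdna


def brute_force_discovery(
    sam_path,
    reference,
    group_of,
    mask_intervals,
    mtdna_contigs,
    min_depth=8,
    flank_len=50,
    clean_zone=20,
    min_minor_reads=3,
    min_minor_fraction=0.04,
    min_group_identity=0.95,
    window_radius=20,
    window_reject=6,
    window_min_allele_reads=2,
):
    """Scan every covered position, recompute every rule, return the
    (pre one-per-contig passing set, final one-per-contig locus set)."""
    base_counts, indel, ambig, _ = tally_sam(sam_path)

    def pooled(key):
        out = defaultdict(int)
        for per_ind in base_counts[key].values():
            for b, n in per_ind.items():
                out[b] += n
        return out

    def is_window_poly(key):
        counts = pooled(key)
        strong = [b for b in ACGT if counts.get(b, 0) >= window_min_allele_reads]
        return len(strong) >= 2

    passing = []
    for key in sorted(base_counts):
        contig, pos = key
        counts = pooled(key)
        alleles = [b for b in ACGT if counts.get(b, 0) >= 1]
        if len(alleles) < 2:
            continue
        ranked = sorted(alleles, key=lambda b: (-counts[b], b))
        major, minor = ranked[0], ranked[1]

        # C1: minor allele unique to one group (strict, zero tolerance)
        group_minor = defaultdict(int)
        group_depth = defaultdict(int)
        for ind, per_ind in base_counts[key].items():
            grp = group_of[ind]
            group_minor[grp] += per_ind.get(minor, 0)
            for b in ACGT:
                group_depth[grp] += per_ind.get(b, 0)
        carriers = [g for g, n in group_minor.items() if n > 0]
        if len(carriers) != 1:
            continue
        focal = carriers[0]

        # C2: pooled read depth (all calls)
        depth_all = sum(counts.values())
        if depth_all < min_depth:
            continue

        # C3: flanks + clean zone
        contig_len = len(reference[contig])
        if pos < flank_len or contig_len - pos - 1 < flank_len:
            continue
        dirty = False
        for p in range(pos - clean_zone, pos + clean_zone + 1):
            if indel.get((contig, p), 0) > 0 or ambig.get((contig, p), 0) > 0:
                dirty = True
        if dirty:
            continue

        # C4: minor allele support
        acgt_depth = sum(counts.get(b, 0) for b in ACGT)
        if counts[minor] < min_minor_reads:
            continue
        if counts[minor] / acgt_depth < min_minor_fraction:
            continue

        # C5: identity within the focal group
        if group_depth[focal] == 0:
            continue
        if group_minor[focal] / group_depth[focal] < min_group_identity:
            continue

        # C6: masks
        if contig in mtdna_contigs:
            continue
        if any(s <= pos < e for s, e in mask_intervals.get(contig, [])):
            continue

        # window filter
        score = 0
        for p in range(pos - window_radius, pos + window_radius + 1):
            if p == pos or (contig, p) not in base_counts:
                continue
            if is_window_poly((contig, p)):
                d = abs(p - pos)
                for lo, hi, w in BANDS:
                    if lo <= d <= hi:
                        score += w
        if score >= window_reject:
            continue

        passing.append((contig, pos, depth_all))

    final = {}
    for contig, pos, depth in passing:
        best = final.get(contig)
        if best is None or (depth, -pos) > (best[1], -best[0]):
            final[contig] = (pos, depth)
    passing_set = {(c, p) for c, p, _ in passing}
    final_set = {(c, p) for c, (p, _) in final.items()}
    return passing_set, final_set
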