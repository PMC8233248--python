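# vetted OA(32,8,4,2): 32 runs, 8 four-level columns, strength 2
# symbols 0-3; column 8 (last) is the blocking factor
# constructed by collapsing disjoint PG(4,2) line triples of the 32-run Hadamard array (seed 0) and verified exhaustively
0,0,0,0,0,0,0,0
3,1,2,0,1,1,2,1
0,3,3,2,1,3,0,2
3,2,1,2,0,2,2,3
0,2,3,2,2,1,1,1
3,3,1,2,3,0,3,0
0,1,0,0,3,2,1,3
3,0,2,0,2,3,3,2
2,0,2,2,1,2,1,0
1,1,0,2,0,3,3,1
2,3,1,0,0,1,1,2
1,2,3,0,1,0,3,3
2,2,1,0,3,3,0,1
1,3,3,0,2,2,2,0
2,1,2,2,2,0,0,3
1,0,0,2,3,1,2,2
1,1,1,1,1,1,0,0
2,0,3,1,0,0,2,1
1,2,2,3,0,2,0,2
2,3,0,3,1,3,2,3
1,3,2,3,3,0,1,1
2,2,0,3,2,1,3,0
1,0,1,1,2,3,1,3
2,1,3,1,3,2,3,2
3,1,3,3,0,3,1,0
0,0,1,3,1,2,3,1
3,2,0,1,1,0,1,2
0,3,2,1,0,1,3,3
3,3,0,1,2,2,0,1
0,2,2,1,3,3,2,0
3,0,3,3,3,1,0,3
0,1,1,3,2,0,2,2
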