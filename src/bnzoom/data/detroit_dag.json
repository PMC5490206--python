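{
 "comment": "Physician-validated Detroit DAG: each arc is parent -> child; factorization P(G|TS,S,B,R) P(T|A,G,B) P(H|T,G,B) P(S|I,B) P(W|A,T) P(B|I,A) P(M|A) P(Y|T) P(P|B) P(I|A) P(R|M) P(IN|M) P(TS|S) P(A).",
 "nodes": ["R", "M", "IN", "W", "Y", "A", "H", "G", "P", "S", "I", "B", "TS", "T"],
 "arcs": [
  ["TS", "G"], ["S", "G"], ["B", "G"], ["R", "G"],
  ["A", "T"], ["G", "T"], ["B", "T"],
  ["T", "H"], ["G", "H"], ["B", "H"],
  ["I", "S"], ["B", "S"],
  ["A", "W"], ["T", "W"],
  ["I", "B"], ["A", "B"],
  ["A", "M"],
  ["T", "Y"],
  ["B", "P"],
  ["A", "I"],
  ["M", "R"],
  ["M", "IN"],
  ["S", "TS"]
 ]
}
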