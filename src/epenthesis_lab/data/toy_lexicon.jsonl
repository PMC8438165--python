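{"phrase_id":"p0000","words":[{"orth_id":"shita1","pos":"Verb","phones":["sh","i0","t","a"]}]}
{"phrase_id":"p0001","words":[{"orth_id":"shita1","pos":"Verb","phones":["sh","i0","t","a"]}]}
{"phrase_id":"p0002","words":[{"orth_id":"shita1","pos":"Verb","phones":["sh","i0","t","a"]}]}
{"phrase_id":"p0003","words":[{"orth_id":"shita1","pos":"Verb","phones":["sh","i0","t","a"]}]}
{"phrase_id":"p0004","words":[{"orth_id":"shita1","pos":"Verb","phones":["sh","i0","t","a"]}]}
{"phrase_id":"p0005","words":[{"orth_id":"shita1","pos":"Verb","phones":["sh","i0","t","a"]}]}
{"phrase_id":"p0006","words":[{"orth_id":"shita1","pos":"Verb","phones":["sh","i0","t","a"]}]}
{"phrase_id":"p0007","words":[{"orth_id":"shita1","pos":"Verb","phones":["sh","t","a"]}]}
{"phrase_id":"p0008","words":[{"orth_id":"shita1","pos":"Verb","phones":["sh","t","a"]}]}
{"phrase_id":"p0009","words":[{"orth_id":"shita1","pos":"Verb","phones":["sh","i","t","a"]}]}
{"phrase_id":"p0010","words":[{"orth_id":"shita2","pos":"Noun","phones":["sh","i0","t","a"]}]}
{"phrase_id":"p0011","words":[{"orth_id":"shita2","pos":"Noun","phones":["sh","i0","t","a"]}]}
{"phrase_id":"p0012","words":[{"orth_id":"shita2","pos":"Noun","phones":["sh","i0","t","a"]}]}
{"phrase_id":"p0013","words":[{"orth_id":"shita2","pos":"Noun","phones":["sh","i0","t","a"]}]}
{"phrase_id":"p0014","words":[{"orth_id":"shita2","pos":"Noun","phones":["sh","i","t","a"]}]}
{"phrase_id":"p0015","words":[{"orth_id":"shita3","pos":"Noun","phones":["sh","i0","t","a"]}]}
{"phrase_id":"p0016","words":[{"orth_id":"shita3","pos":"Noun","phones":["sh","t","a"]}]}
{"phrase_id":"p0017","words":[{"orth_id":"aru","pos":"Verb","phones":["a","r","u"]}]}
{"phrase_id":"p0018","words":[{"orth_id":"aru","pos":"Verb","phones":["a","r","u"]}]}
{"phrase_id":"p0019","words":[{"orth_id":"aru","pos":"Verb","phones":["a","r","u"]}]}
{"phrase_id":"p0020","words":[{"orth_id":"aru","pos":"Verb","phones":["a","r","u"]}]}
{"phrase_id":"p0021","words":[{"orth_id":"aru","pos":"Verb","phones":["a","r","u"]}]}
{"phrase_id":"p0022","words":[{"orth_id":"aru","pos":"Verb","phones":["a","r","u"]}]}
{"phrase_id":"p0023","words":[{"orth_id":"aru","pos":"Verb","phones":["a","r","u"]}]}
{"phrase_id":"p0024","words":[{"orth_id":"aru","pos":"Verb","phones":["a","r","u"]}]}
{"phrase_id":"p0025","words":[{"orth_id":"aru","pos":"Verb","phones":["a","r","u"]}]}
{"phrase_id":"p0026","words":[{"orth_id":"aru","pos":"Verb","phones":["a","r","u"]}]}
{"phrase_id":"p0027","words":[{"orth_id":"aru","pos":"Adjective","phones":["a","r","u"]}]}
{"phrase_id":"p0028","words":[{"orth_id":"aru","pos":"Adjective","phones":["a","r","u"]}]}
{"phrase_id":"p0029","words":[{"orth_id":"aru","pos":"Adjective","phones":["a","r","u"]}]}
{"phrase_id":"p0030","words":[{"orth_id":"aru","pos":"Adjective","phones":["a","r","u"]}]}
{"phrase_id":"p0031","words":[{"orth_id":"aru","pos":"Adjective","phones":["a","r","u"]}]}
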