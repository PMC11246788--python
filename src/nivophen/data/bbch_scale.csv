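code,morphotype,description
0,A,Plants not visible
0,P,Plants not visible
0,G,Plants not visible
9,A,Emergence: cotyledons break through soil surface
9,P,Bud shows green tips
9,G,Emergence: coleoptile breaks through soil surface
10,A,Cotyledons completely unfolded
10,P,First leaves separated
10,G,First true leaf emerged from coleoptile
11,A,"First true leaf, leaf pair or whorl unfolded"
11,P,"First true leaf, leaf pair or whorl unfolded"
11,G,"First true leaf, leaf pair or whorl unfolded"
12,A,"2 true leaves, leaf pairs or whorls unfolded"
12,P,"2 true leaves, leaf pairs or whorls unfolded"
12,G,"2 true leaves, leaf pairs or whorls unfolded"
13,A,"3 true leaves, leaf pairs or whorls unfolded"
13,P,"3 true leaves, leaf pairs or whorls unfolded"
13,G,"3 true leaves, leaf pairs or whorls unfolded"
14,A,Leaf development continues
14,P,Leaf development continues
14,G,Leaf development continues
15,A,Leaf development continues
15,P,Leaf development continues
15,G,Leaf development continues
16,A,Leaf development continues
16,P,Leaf development continues
16,G,Leaf development continues
17,A,Leaf development continues
17,P,Leaf development continues
17,G,Leaf development continues
18,A,Leaf development continues
18,P,Leaf development continues
18,G,Leaf development continues
19,A,"More true leaves, leaf pairs, or whorls unfolded"
19,P,"More true leaves, leaf pairs, or whorls unfolded"
19,G,"More true leaves, leaf pairs, or whorls unfolded"
20,A,Inflorescence or flower buds visible (soil level)
20,P,Inflorescence or flower buds visible (soil level)
20,G,Beginning of heading
23,A,Inflorescence or flower buds visible (beginning of elongation)
23,P,Inflorescence or flower buds visible (beginning of elongation)
23,G,Less than a half of inflorescence emerged
25,A,First individual flowers/flower styles visible (still closed)
25,P,First individual flowers/flower styles visible (still closed)
25,G,Half of inflorescence emerged (middle of heading)
29,A,First flower petals/flower visible (in petalled forms)
29,P,First flower petals/flower visible (in petalled forms)
29,G,Inflorescence fully emerged (end of heading)
30,A,First flowers open (sporadically)
30,P,First flowers open (sporadically)
30,G,"First stamens/bulbils visible (sporadically), sheaf still closed"
33,A,<50% of flowers open
33,P,<50% of flowers open
33,G,"<50% of stamens/bulbils visible, sheaf begins to open"
35,A,">50% of flowers open, first petals may be fallen"
35,P,">50% of flowers open, first petals may be fallen"
35,G,">50% of stamens/bulbils visible, opened sheaf"
37,A,Majority of petals dry or fallen
37,P,Majority of petals dry or fallen
37,G,Majority of stamens fallen/stem may begin to bend
39,A,End of flowering: fruit set visible
39,P,End of flowering: fruit set visible
39,G,End of flowering: fruit set visible/bent stem
40,A,Fruit visible (unripe)
40,P,Fruit visible (unripe)
40,G,Caryopsis watery ripe
43,A,<50% have reached the final size
43,P,<50% have reached the final size
43,G,Early milk
45,A,>50% have reached the final size
45,P,>50% have reached the final size
45,G,"Milky ripe, medium milk"
47,G,Late milk
49,A,Nearly all fruits have reached the final size
49,P,Nearly all fruits have reached the final size
49,G,Nearly all caryopses have reached the final size
50,A,Beginning of fruit abscission
50,P,Beginning of fruit abscission
50,G,Beginning of dissemination (first glumes may be dry and empty)
53,A,<50% of seed dissemination
53,P,<50% of seed dissemination
53,G,<50% of caryopsis/bulbils disseminated
55,A,>50% of seed dissemination
55,P,>50% of seed dissemination
55,G,>50% of caryopsis/bulbils disseminated
59,A,Full dissemination
59,P,Full dissemination
59,G,Full dissemination (glumes totally dry and empty)
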