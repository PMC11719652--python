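37~43<2n>,XY,der(2)t(2;19)(q34;p11),-3,der(4)t(3;4)(q?22;p11),-4,+7,-8,+der(12)(12pter->12q1?2::2q?2->2q?2::10q?3->10qter),+der(12)(12pter->12q1?2::2q?2->2q?2::2q?2->2q?2::19p11->19pter),+der(19)(19qter->19p11::2q?2->2q?2::6q11->6qter)[cp30]
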