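<?xml version="1.0" encoding="utf-8"?>
<aiml version="subset-1.0">
  <topic name="pwad_profile" description="información personal del paciente (cumpleaños, apodo, lugar de nacimiento)">
    <category role="trigger">
      <pattern>CUMPLEAÑOS</pattern>
      <template><random>
        <li>¡Qué buen tema! ¿Es cierto que naciste en <get name="lugar_nacimiento"/>?</li>
        <li>Hablar de ti es muy bonito. ¿Dónde celebraste tu último cumpleaños?</li>
      </random></template>
    </category>
    <category role="trigger">
      <pattern>_ CUMPLEAÑOS</pattern>
      <template><srai>CUMPLEAÑOS</srai></template>
    </category>
    <category role="trigger">
      <pattern>CUMPLEAÑOS _</pattern>
      <template><srai>CUMPLEAÑOS</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ CUMPLEAÑOS _</pattern>
      <template><srai>CUMPLEAÑOS</srai></template>
    </category>
    <category role="trigger">
      <pattern>APODO</pattern>
      <template><srai>CUMPLEAÑOS</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ APODO</pattern>
      <template><srai>CUMPLEAÑOS</srai></template>
    </category>
    <category role="trigger">
      <pattern>APODO _</pattern>
      <template><srai>CUMPLEAÑOS</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ APODO _</pattern>
      <template><srai>CUMPLEAÑOS</srai></template>
    </category>
    <category role="trigger">
      <pattern>NACÍ</pattern>
      <template><srai>CUMPLEAÑOS</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ NACÍ</pattern>
      <template><srai>CUMPLEAÑOS</srai></template>
    </category>
    <category role="trigger">
      <pattern>NACÍ _</pattern>
      <template><srai>CUMPLEAÑOS</srai></template>
    </category>
    <category role="trigger">
      <pattern>_ NACÍ _</pattern>
      <template><srai>CUMPLEAÑOS</srai></template>
    </category>
    <category>
      <pattern>SÍ</pattern>
      <template><random>
        <li>¡Lo sabía! ¿Qué recuerdos tienes de <get name="lugar_nacimiento"/>?</li>
        <li>¿Y te gusta que te digan <get name="apodo"/>?</li>
      </random></template>
    </category>
    <category>
      <pattern>SI</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SÍ _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>SI _</pattern>
      <template><srai>SÍ</srai></template>
    </category>
    <category>
      <pattern>NO</pattern>
      <template>Gracias por decírmelo. ¿Me cuentas dónde naciste?</template>
    </category>
    <category role="fallback">
      <pattern>*</pattern>
      <template><random>
        <li>Me encanta conocerte mejor. ¿Me platicas algo más de ti?</li>
        <li>Qué interesante. ¿Qué más te gustaría contarme de tu vida?</li>
      </random></template>
    </category>
  </topic>
</aiml>
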